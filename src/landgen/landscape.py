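"""Competing landscape hypotheses for genetic differentiation.

Given a genetic distance matrix and a set of predictor matrices
(geographic, environmental by category, externally computed
resistance), this module ranks isolation-by-distance /
-environment / -resistance models with Mantel and partial Mantel
tests, reciprocal causal modeling, and maximum-likelihood
population-effects (MLPE) regressions compared by AIC. It also
provides spatial eigenvector construction (PCNM), three-set partial-RDA
variance partitioning, niche-overlap statistics with a permutation
equivalency test, TSS thresholding for suitability maps, and
VIF/correlation collinearity pruning of environmental tables.

Permutation p-values use the (1 + count) / (1 + n_perm) convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.sparse.csgraph import minimum_spanning_tree

from .distmat import DistanceMatrix
from .envtable import EnvTable


# ------------------------------------------------------------ collinearity


def _vif(x: np.ndarray) -> np.ndarray:
    """Variance inflation factor per column of a z-scored matrix."""
    n, p = x.shape
    out = np.empty(p)
    for j in range(p):
        others = np.delete(x, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ coef
        ss_tot = (x[:, j] ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def prune_collinear(
    env: EnvTable, vif_max: float = 10.0, r_max: float = 0.8
) -> tuple[EnvTable, list[tuple[str, str]]]:
    """Drop collinear variables: first iteratively by highest VIF until
    all VIF <= vif_max, then one member of each remaining pair with
    |r| > r_max (the higher mean-|r| member goes). Returns the pruned
    table and the drop log as (variable, reason) in drop order."""
    if len(env.variables) < 2:
        return env, []
    report: list[tuple[str, str]] = []
    keep = list(env.variables)
    z = env.zscored()

    vif_possible = env.n_sites > len(keep)
    if not vif_possible:
        warnings.warn("fewer sites than variables: VIF skipped, correlation-only pruning")
    while vif_possible and len(keep) >= 2:
        x = z.subset(keep).values()
        vifs = _vif(x)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_max:
            break
        report.append((keep[worst], f"VIF={vifs[worst]:.2f}>{vif_max:g}"))
        keep.pop(worst)

    while len(keep) >= 2:
        x = z.subset(keep).values()
        r = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(r, 0.0)
        absr = np.abs(r)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= r_max:
            break
        # keep the member less entangled with everything else
        drop = i if absr[i].mean() >= absr[j].mean() else j
        partner = j if drop == i else i
        report.append((keep[drop], f"|r|={absr[i, j]:.3f}>{r_max:g} with {keep[partner]}"))
        keep.pop(drop)

    return env.subset(keep), report


# ----------------------------------------------------------------- Mantel


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


def _check_same_labels(*mats: DistanceMatrix) -> None:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError("distance matrices must share labels in the same order")


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int | str = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    Pearson r over the off-diagonal upper triangle; significance by
    jointly permuting rows/columns of ``b``. ``n_perm="exact"``
    enumerates all n! relabelings (p = count / n!, identity included).
    """
    _check_same_labels(a, b)
    va, vb_mat = a.condensed(), b.values
    vb = b.condensed()
    if va.std() == 0.0 or vb.std() == 0.0:
        raise ValueError("zero variance in a distance triangle: correlation undefined")
    obs = float(np.corrcoef(va, vb)[0, 1])
    n = a.n
    iu = np.triu_indices(n, 1)

    def perm_r(order: np.ndarray) -> float:
        return float(np.corrcoef(va, vb_mat[np.ix_(order, order)][iu])[0, 1])

    if n_perm == "exact":
        rs = np.array([perm_r(np.array(p)) for p in itertools.permutations(range(n))])
        count = int(_count_extreme(rs, obs, alternative))
        return MantelResult(obs, count / len(rs), len(rs))
    rng = np.random.default_rng(seed)
    rs = np.array([perm_r(rng.permutation(n)) for _ in range(int(n_perm))])
    count = int(_count_extreme(rs, obs, alternative))
    return MantelResult(obs, (1 + count) / (1 + int(n_perm)), int(n_perm))


def _count_extreme(rs: np.ndarray, obs: float, alternative: str) -> int:
    eps = 1e-12
    if alternative == "greater":
        return int((rs >= obs - eps).sum())
    if alternative == "less":
        return int((rs <= obs + eps).sum())
    return int((np.abs(rs) >= abs(obs) - eps).sum())


def _triangle_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    slope, intercept = np.polyfit(x, y, 1)
    return y - (slope * x + intercept)


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    control: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel: correlation of the residuals of a ~ control and
    b ~ control over the triangle; permutation applied to the residual
    matrix of ``a`` (residual-permutation scheme)."""
    _check_same_labels(a, b, control)
    va, vb, vc = a.condensed(), b.condensed(), control.condensed()
    for v, name in ((va, "a"), (vb, "b")):
        if v.std() == 0.0:
            raise ValueError(f"zero variance in matrix {name}: correlation undefined")
    if vc.std() == 0.0:
        # vacuous control: falls back to the simple Mantel correlation
        resid_a, resid_b = va - va.mean(), vb - vb.mean()
    else:
        resid_a = _triangle_residuals(va, vc)
        resid_b = _triangle_residuals(vb, vc)
    # a matrix fully explained by the control leaves only rounding noise:
    # its partial correlation is 0 by convention, not a random sign
    if resid_a.std() <= 1e-10 * max(va.std(), 1e-30) or resid_b.std() <= 1e-10 * max(vb.std(), 1e-30):
        return MantelResult(0.0, 1.0, int(n_perm) if n_perm != "exact" else 0)
    obs = float(np.corrcoef(resid_a, resid_b)[0, 1])

    n = a.n
    iu = np.triu_indices(n, 1)
    ra_mat = np.zeros((n, n))
    ra_mat[iu] = resid_a
    ra_mat += ra_mat.T
    rng = np.random.default_rng(seed)
    rs = np.empty(int(n_perm))
    for t in range(int(n_perm)):
        order = rng.permutation(n)
        rs[t] = np.corrcoef(ra_mat[np.ix_(order, order)][iu], resid_b)[0, 1]
    count = int(_count_extreme(rs, obs, alternative))
    return MantelResult(obs, (1 + count) / (1 + int(n_perm)), int(n_perm))


# -------------------------------------------------- reciprocal causal model


def rcm(
    genetic: DistanceMatrix,
    models: dict[str, DistanceMatrix],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Reciprocal causal modeling support matrix.

    entry(f, a) = r_partial(genetic ~ f | a) - r_partial(genetic ~ a | f).
    A focal model is fully supported when its whole off-diagonal row is
    positive. Degenerate (zero-variance) models yield NaN rows/columns.
    """
    names = list(models)
    if len(names) < 1:
        raise ValueError("need at least one model")
    out = pd.DataFrame(0.0, index=names, columns=names)
    for f, a in itertools.combinations(names, 2):
        try:
            r_fa = partial_mantel(genetic, models[f], models[a], n_perm=1, seed=seed).r
            r_af = partial_mantel(genetic, models[a], models[f], n_perm=1, seed=seed).r
            val = r_fa - r_af
        except ValueError:
            val = np.nan
        out.loc[f, a] = val
        out.loc[a, f] = -val
    return out


def fully_supported(support: pd.DataFrame) -> list[str]:
    """Models whose entire off-diagonal support row is positive."""
    winners = []
    for f in support.index:
        row = support.loc[f].drop(f)
        if len(row) and (row > 0).all():
            winners.append(f)
    return winners


# ------------------------------------------------------------------- MLPE


@dataclass
class MlpeFit:
    name: str
    intercept: float
    slope: float
    slope_se: float
    rho: float
    sigma2: float
    loglik: float
    aic: float
    k: int = 4


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, 1)
    return iu[0], iu[1]


def _mlpe_corr(n: int) -> np.ndarray:
    """Base correlation structure C: diag 1, 1/2 for pairs sharing a
    population, 0 otherwise (C = Z Z^T / 2 with Z the pair-population
    incidence; positive semidefinite by construction)."""
    ii, jj = _pair_index(n)
    m = len(ii)
    z = np.zeros((m, n))
    z[np.arange(m), ii] = 1.0
    z[np.arange(m), jj] = 1.0
    return z @ z.T / 2.0


def _mlpe_loglik(y: np.ndarray, x: np.ndarray, c: np.ndarray, rho: float):
    m = len(y)
    v = (1.0 - rho) * np.eye(m) + rho * c
    try:
        chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return -np.inf, None
    wi_y = np.linalg.solve(chol, y)
    wi_x = np.linalg.solve(chol, x)
    xtvx = wi_x.T @ wi_x
    beta = np.linalg.solve(xtvx, wi_x.T @ wi_y)
    resid = wi_y - wi_x @ beta
    rss = float(resid @ resid)
    sigma2 = rss / m
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    loglik = -0.5 * (m * np.log(2.0 * np.pi * sigma2) + logdet + m)
    cov_beta = np.linalg.inv(xtvx) * sigma2
    return loglik, (beta, sigma2, cov_beta)


def mlpe_fit(
    genetic: DistanceMatrix,
    predictors: dict[str, DistanceMatrix],
    rho: float | None = None,
) -> pd.DataFrame:
    """Fit an MLPE regression of pairwise genetic distance on each
    predictor and rank by AIC.

    The covariance follows Clarke's population-effects structure: the
    correlation between two pairwise observations sharing one
    population is rho/2 on the working scale; rho is profiled over
    [0, 0.99] by maximum likelihood (``rho=`` fixes it instead, e.g. 0
    reduces to OLS). AIC counts k = 4 (intercept, slope, rho, sigma2).
    The ranking applies the dAIC > 2 distinctness convention via the
    ``distinct_from_best`` column.
    """
    n = genetic.n
    y = genetic.condensed()
    c = _mlpe_corr(n)
    fits: list[MlpeFit] = []
    for name, pred in predictors.items():
        _check_same_labels(genetic, pred)
        xv = pred.condensed()
        sd = xv.std()
        xs = (xv - xv.mean()) / (sd if sd > 0 else 1.0)
        x = np.column_stack([np.ones_like(xs), xs])

        if rho is not None:
            ll, parts = _mlpe_loglik(y, x, c, rho)
            best_rho = rho
        else:
            neg = lambda r: -_mlpe_loglik(y, x, c, r)[0]
            res = optimize.minimize_scalar(neg, bounds=(0.0, 0.99), method="bounded")
            best_rho = float(res.x)
            ll, parts = _mlpe_loglik(y, x, c, best_rho)
            if parts is None:  # retry from the OLS end of the range
                ll, parts = _mlpe_loglik(y, x, c, 0.0)
                best_rho = 0.0
        if parts is None:
            raise RuntimeError(f"MLPE covariance not positive definite for model {name!r}")
        beta, sigma2, cov_beta = parts
        fits.append(
            MlpeFit(
                name=name,
                intercept=float(beta[0]),
                slope=float(beta[1]),
                slope_se=float(np.sqrt(cov_beta[1, 1])),
                rho=best_rho,
                sigma2=float(sigma2),
                loglik=float(ll),
                aic=float(2 * 4 - 2 * ll),
            )
        )
    table = pd.DataFrame([f.__dict__ for f in fits]).set_index("name").sort_values("aic")
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    table["distinct_from_best"] = table["delta_aic"] > 2.0
    return table


# ------------------------------------------------------------------- PCNM


@dataclass
class PcnmResult:
    vectors: pd.DataFrame  # sites x PCNM axes (unit-norm eigenvectors)
    eigenvalues: np.ndarray
    truncation: float

    def half_positive(self) -> pd.DataFrame:
        """First floor(n_positive / 2) axes, the conventional subset."""
        k = len(self.eigenvalues) // 2
        return self.vectors.iloc[:, :k] if k else self.vectors.iloc[:, :0]


def pcnm(geo: DistanceMatrix, truncation: float | None = None) -> PcnmResult:
    """Principal coordinates of neighbour matrices (spatial eigenvectors).

    Distances above the truncation (default: the largest minimum
    spanning tree edge) are replaced by 4x the truncation; the
    modified matrix is double-centered and eigendecomposed; axes with
    positive eigenvalues are returned in decreasing order.
    """
    if geo.n < 3:
        raise ValueError("need at least 3 sites")
    d = geo.values.copy()
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    if truncation <= 0:
        raise ValueError("truncation must be positive")
    d[d > truncation] = 4.0 * truncation
    np.fill_diagonal(d, 0.0)
    n = geo.n
    j = np.eye(n) - np.ones((n, n)) / n
    gmat = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(gmat)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-9
    pos = vals > tol
    cols = [f"PCNM{i + 1}" for i in range(int(pos.sum()))]
    return PcnmResult(
        pd.DataFrame(vecs[:, pos], index=geo.labels, columns=cols), vals[pos], truncation
    )


# ----------------------------------------------------- variance partition


@dataclass
class VariancePartition:
    fractions: pd.Series  # a, b, c, ab, bc, ac, abc, residual
    adj_r2: pd.Series  # the 7 subset models
    p_full: float
    p_pure: pd.Series  # permutation p for each pure fraction
    n_permutations: int


def _project_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """R^2 of the least-squares projection of centered Y onto span(X)."""
    xc = x - x.mean(axis=0)
    q, r = np.linalg.qr(xc)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())).sum())
    if rank < xc.shape[1]:
        warnings.warn("rank-deficient predictor set; using pseudoinverse projection")
    coef = np.linalg.pinv(xc) @ y
    fitted = xc @ coef
    return float((fitted**2).sum() / (y**2).sum()), rank


def _adjusted_r2(r2: float, n: int, p_rank: int) -> float:
    if n - p_rank - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_rank - 1)


def rda_partition(
    response: np.ndarray | pd.DataFrame,
    set_a: np.ndarray | pd.DataFrame,
    set_b: np.ndarray | pd.DataFrame,
    set_c: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> VariancePartition:
    """Three-set variance partitioning by partial redundancy analysis.

    Adjusted R^2 (Ezekiel) is computed for the 7 subset models and the
    8 fractions (3 pure, 3 pairwise-joint, 1 three-way, residual)
    recovered by inclusion–exclusion. The full model is tested by
    permuting response rows; each pure fraction by permuting the
    residuals of the response on the other two sets.
    """
    y = np.asarray(response, dtype=float)
    y = y - y.mean(axis=0)
    if (y**2).sum() == 0:
        raise ValueError("response has no variance")
    sets = {"A": np.atleast_2d(np.asarray(set_a, float)), "B": np.atleast_2d(np.asarray(set_b, float)),
            "C": np.atleast_2d(np.asarray(set_c, float))}
    for k, v in sets.items():
        if v.shape[0] != y.shape[0]:
            sets[k] = v.T
        if sets[k].shape[0] != y.shape[0]:
            raise ValueError(f"set {k} rows do not align with response")
    n = y.shape[0]

    combos = ["A", "B", "C", "AB", "AC", "BC", "ABC"]
    adj: dict[str, float] = {}
    ranks: dict[str, int] = {}
    for combo in combos:
        x = np.hstack([sets[s] for s in combo])
        r2, rank = _project_r2(y, x)
        ranks[combo] = rank
        adj[combo] = _adjusted_r2(r2, n, rank)

    # solve for the 7 elementary fractions from the subset adj R^2
    frac_names = ["a", "b", "c", "ab", "ac", "bc", "abc"]
    membership = {
        "A": ["a", "ab", "ac", "abc"],
        "B": ["b", "ab", "bc", "abc"],
        "C": ["c", "ac", "bc", "abc"],
        "AB": ["a", "b", "ab", "ac", "bc", "abc"],
        "AC": ["a", "c", "ab", "ac", "bc", "abc"],
        "BC": ["b", "c", "ab", "ac", "bc", "abc"],
        "ABC": frac_names,
    }
    mat = np.array([[1.0 if f in membership[cm] else 0.0 for f in frac_names] for cm in combos])
    sol = np.linalg.solve(mat, np.array([adj[cm] for cm in combos]))
    fractions = pd.Series(sol, index=frac_names)
    fractions["residual"] = 1.0 - adj["ABC"]

    rng = np.random.default_rng(seed)
    p_full = _permute_full(y, np.hstack([sets["A"], sets["B"], sets["C"]]), n_perm, rng)
    p_pure = {}
    for pure, others in (("a", "BC"), ("b", "AC"), ("c", "AB")):
        target = sets[pure.upper()]
        cond = np.hstack([sets[s] for s in others])
        p_pure[pure] = _permute_partial(y, target, cond, n_perm, rng)
    return VariancePartition(
        fractions=fractions,
        adj_r2=pd.Series(adj),
        p_full=p_full,
        p_pure=pd.Series(p_pure),
        n_permutations=n_perm,
    )


def _rda_f(y: np.ndarray, x: np.ndarray) -> float:
    r2, rank = _project_r2(y, x)
    n = y.shape[0]
    dfr = max(n - rank - 1, 1)
    return (r2 / max(rank, 1)) / (max(1.0 - r2, 1e-12) / dfr)


def _permute_full(y: np.ndarray, x: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    obs = _rda_f(y, x)
    count = sum(_rda_f(y[rng.permutation(len(y))], x) >= obs for _ in range(n_perm))
    return (1 + count) / (1 + n_perm)


def _permute_partial(
    y: np.ndarray, target: np.ndarray, cond: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Partial F of target | cond with permutation of conditional residuals."""
    condc = cond - cond.mean(axis=0)
    fit_cond = condc @ (np.linalg.pinv(condc) @ y)
    resid = y - fit_cond

    def partial_f(res: np.ndarray) -> float:
        full_x = np.hstack([cond, target])
        yy = fit_cond + res
        yy = yy - yy.mean(axis=0)
        r2_full, rank_full = _project_r2(yy, full_x)
        r2_cond, rank_cond = _project_r2(yy, cond)
        df_t = max(rank_full - rank_cond, 1)
        df_r = max(len(yy) - rank_full - 1, 1)
        return ((r2_full - r2_cond) / df_t) / (max(1.0 - r2_full, 1e-12) / df_r)

    obs = partial_f(resid)
    count = sum(partial_f(resid[rng.permutation(len(resid))]) >= obs for _ in range(n_perm))
    return (1 + count) / (1 + n_perm)


# ---------------------------------------------------------- niche overlap


@dataclass
class NicheOverlapResult:
    d: float
    i: float
    p_equivalency_d: float | None = None
    p_equivalency_i: float | None = None
    n_permutations: int = 0


def _normalize_density(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("densities must be nonnegative")
    total = z.sum()
    if total == 0:
        raise ValueError("all-zero density grid")
    return z / total


def schoener_d(z1: np.ndarray, z2: np.ndarray) -> float:
    z1, z2 = _normalize_density(z1), _normalize_density(z2)
    return float(1.0 - 0.5 * np.abs(z1 - z2).sum())


def warren_i(z1: np.ndarray, z2: np.ndarray) -> float:
    z1, z2 = _normalize_density(z1), _normalize_density(z2)
    return float(1.0 - 0.5 * ((np.sqrt(z1) - np.sqrt(z2)) ** 2).sum())


def occurrence_density(
    points: np.ndarray, bins: tuple[int, int], extent: tuple[float, float, float, float],
    bandwidth: float = 1.0,
) -> np.ndarray:
    """Smoothed occurrence-density grid from points in (x, y) columns."""
    from scipy.ndimage import gaussian_filter

    pts = np.asarray(points, dtype=float)
    h, _, _ = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=bins, range=[extent[:2], extent[2:]]
    )
    return _normalize_density(gaussian_filter(h, sigma=bandwidth))


def niche_overlap(
    dens1: np.ndarray,
    dens2: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    points: tuple[np.ndarray, np.ndarray] | None = None,
    density_builder=None,
) -> NicheOverlapResult:
    """Schoener's D and Warren's I, with an optional equivalency test.

    The equivalency test needs the occurrence points behind the two
    density grids and a ``density_builder(points) -> grid`` callable:
    points are pooled, group labels reassigned at random, densities
    rebuilt, and the overlap recomputed; p is two-sided.
    """
    d_obs = schoener_d(dens1, dens2)
    i_obs = warren_i(dens1, dens2)
    if points is None:
        return NicheOverlapResult(d_obs, i_obs)
    if density_builder is None:
        raise ValueError("equivalency test requires a density_builder")
    p1, p2 = (np.asarray(p, dtype=float) for p in points)
    pooled = np.vstack([p1, p2])
    n1 = len(p1)
    rng = np.random.default_rng(seed)
    d_perm = np.empty(n_perm)
    i_perm = np.empty(n_perm)
    for t in range(n_perm):
        order = rng.permutation(len(pooled))
        g1, g2 = pooled[order[:n1]], pooled[order[n1:]]
        z1, z2 = density_builder(g1), density_builder(g2)
        d_perm[t] = schoener_d(z1, z2)
        i_perm[t] = warren_i(z1, z2)

    def two_sided(perm: np.ndarray, obs: float) -> float:
        lo = (1 + (perm <= obs + 1e-12).sum()) / (1 + n_perm)
        hi = (1 + (perm >= obs - 1e-12).sum()) / (1 + n_perm)
        return min(2.0 * min(lo, hi), 1.0)

    return NicheOverlapResult(
        d_obs, i_obs, two_sided(d_perm, d_obs), two_sided(i_perm, i_obs), n_perm
    )


# ------------------------------------------------------------- TSS


def tss_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing sensitivity + specificity (max TSS).

    ``scores >= threshold`` predicts presence. Ties take the lowest
    score. Returns (threshold, TSS at threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_t, best_tss = None, -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_t, best_tss = float(t), float(tss)
    return best_t, best_tss


def binarize(grid: np.ndarray, threshold: float) -> np.ndarray:
    """Apply a TSS threshold to a suitability grid (NaN stays NaN)."""
    out = np.where(np.isnan(grid), np.nan, (grid >= threshold).astype(float))
    return out
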