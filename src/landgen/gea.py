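"""Genotype–environment association scans and outlier calling.

Two complementary scans: a ridge latent-factor mixed model (LFMM) that
tests each locus against each environmental variable while K latent
factors absorb population structure, and a PCA-outlier scan that flags
loci whose loadings on the top K genotype PCs are multivariate
outliers (robust Mahalanobis distance). Both are calibrated by the
genomic inflation factor. Putative adaptive loci are the intersection
of the environment-associated set with the union of differentiation
outlier sets, which may include externally computed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .envtable import EnvTable
from .genotypes import GenotypeMatrix


@dataclass
class AssociationResult:
    effect: pd.DataFrame  # loci x variables
    z: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    gif: pd.Series  # genomic inflation factor per variable
    k: int
    n_runs: int

    def significant(self, q_threshold: float = 0.10) -> "OutlierSet":
        """Loci with q < threshold for at least one variable."""
        hit = self.q < q_threshold
        ids = [lid for lid, any_hit in hit.any(axis=1).items() if any_hit]
        prov = {lid: [v for v in hit.columns if hit.at[lid, v]] for lid in ids}
        return OutlierSet(ids, "lfmm" if self.q.shape[1] > 1 or "pcadapt" not in self.q.columns else "pcadapt",
                          {"q_threshold": q_threshold}, prov)


@dataclass
class OutlierSet:
    ids: list[str]
    method: str  # lfmm | pcadapt | external
    threshold: dict = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = list(dict.fromkeys(self.ids))

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.ids) + ("\n" if self.ids else ""))

    @classmethod
    def read(cls, path: str | Path, method: str = "external") -> "OutlierSet":
        ids = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
        return cls(ids, method)


# ------------------------------------------------------------------ BH-FDR


def bh_fdr(p_values: np.ndarray, q_threshold: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: q-values (monotone from the largest p
    down) and the rejection set at ``q_threshold``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < q_threshold


CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)


def genomic_inflation(z: np.ndarray) -> float:
    """lambda = median(z^2) / median of chi-square(1)."""
    return float(np.median(np.asarray(z) ** 2) / CHI2_MEDIAN_1DF)


# ------------------------------------------------------------------- LFMM


def _latent_factors(y: np.ndarray, x: np.ndarray, k: int, ridge: float) -> np.ndarray:
    """Rank-K latent factor scores from the ridge-shrunken projection of
    the genotype matrix off the environmental design (SVD closed form)."""
    if k == 0:
        return np.empty((y.shape[0], 0))
    q, sv, _ = np.linalg.svd(x, full_matrices=False)
    delta = np.sqrt(ridge / (ridge + sv**2))
    proj = y - q @ ((1.0 - delta)[:, None] * (q.T @ y))
    u, s, _ = np.linalg.svd(proj, full_matrices=False)
    return u[:, :k] * s[:k]


def _locus_regression(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus OLS of each genotype column on the design; returns the
    first-column effect and its t statistic."""
    n, p = design.shape
    xtx = design.T @ design
    xtx_inv = np.linalg.pinv(xtx)
    coef = xtx_inv @ (design.T @ y)  # (p, L)
    resid = y - design @ coef
    df = max(n - p - 1, 1)  # columns are centered; one df for the implicit intercept
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[0, 0], 1e-300))
    return coef[0], coef[0] / se


def fit_lfmm(
    g: GenotypeMatrix,
    env: EnvTable,
    k: int = 2,
    ridge_penalty: float = 1e-5,
    n_runs: int = 10,
    seed: int = 0,
    calibrate: bool = True,
    q_threshold: float = 0.10,
) -> AssociationResult:
    """Ridge LFMM scan of every locus against every environmental variable.

    Each variable is tested univariately: latent factors of rank ``k``
    are estimated from the genotype matrix after shrinking out the
    variable's ridge projection, then each locus is regressed on
    [variable, factors]. Run 1 uses the full data; the remaining
    ``n_runs - 1`` runs bootstrap individuals, and per-locus z-scores
    are combined as the across-run median. p-values come from the
    combined z after division of z^2 by the genomic inflation factor.

    With ``calibrate=False`` and ``n_runs=1`` the p-values are exact
    per-locus regression t-test p-values, so ``k=0`` reproduces
    ordinary simple linear regression.
    """
    if env.n_sites != g.n_individuals:
        raise ValueError("env rows must align with individuals")
    if k < 0 or k >= min(g.n_individuals, g.n_loci):
        raise ValueError("K must satisfy 0 <= K < min(n_individuals, n_loci)")
    const = env.constant_variables()
    if const:
        raise ValueError(f"constant environmental variable(s): {const}")
    y_full = g.imputed()
    y_full = y_full - y_full.mean(axis=0)
    envz = env.zscored().values()
    rng = np.random.default_rng(seed)
    n = g.n_individuals

    eff = {}
    zs = {}
    ps = {}
    qs = {}
    gifs = {}
    for vi, var in enumerate(env.variables):
        run_z = []
        run_eff = []
        for run in range(n_runs):
            idx = np.arange(n) if run == 0 else rng.integers(0, n, size=n)
            y = y_full[idx]
            y = y - y.mean(axis=0)
            x = envz[idx, vi:vi + 1]
            x = x - x.mean(axis=0)
            if x.std() == 0.0:
                continue  # degenerate bootstrap draw
            x = x / x.std()
            u = _latent_factors(y, x, k, ridge_penalty)
            design = np.column_stack([x, u])
            beta, t = _locus_regression(y, design)
            run_z.append(t)
            run_eff.append(beta)
        z = np.median(np.vstack(run_z), axis=0)
        beta = np.median(np.vstack(run_eff), axis=0)
        if calibrate:
            gif = genomic_inflation(z)
            p = stats.chi2.sf(z**2 / gif, 1)
        else:
            gif = genomic_inflation(z)
            df = max(n - (k + 1) - 1, 1)
            p = 2.0 * stats.t.sf(np.abs(z), df)
        q, _ = bh_fdr(p, q_threshold)
        eff[var], zs[var], ps[var], qs[var], gifs[var] = beta, z, p, q, gif

    ids = g.locus_ids
    return AssociationResult(
        effect=pd.DataFrame(eff, index=ids),
        z=pd.DataFrame(zs, index=ids),
        p=pd.DataFrame(ps, index=ids),
        q=pd.DataFrame(qs, index=ids),
        gif=pd.Series(gifs),
        k=k,
        n_runs=n_runs,
    )


# ---------------------------------------------------------------- pcadapt


def pcadapt_scan(
    g: GenotypeMatrix, k: int = 2, q_threshold: float = 0.10, mcd_support: float = 0.75, seed: int = 0
) -> AssociationResult:
    """PCA differentiation-outlier scan (Mahalanobis on loading z-scores).

    Each locus is regressed on the top-K genotype PC scores; the K
    per-locus z-scores are summarized by a squared Mahalanobis distance
    under a robust (minimum covariance determinant) covariance, and
    p-values come from chi-square(K) after genomic-inflation rescaling.
    The result is reported under the single pseudo-variable "pcadapt".
    """
    y = g.imputed()
    y = y - y.mean(axis=0)
    sd = y.std(axis=0)
    poly = sd > 0
    u, s, _ = np.linalg.svd(y / np.where(sd == 0, 1.0, sd), full_matrices=False)
    max_k = int((s > 1e-10).sum())
    if k < 1 or k > max_k:
        raise ValueError(f"K must be in [1, {max_k}]")
    scores = u[:, :k] * s[:k]
    scores = scores - scores.mean(axis=0)
    _, zmat = _multi_regression_z(y, scores)

    zz = zmat[poly]
    if k == 1:
        # 1-D case: statistic proportional to the squared standardized
        # loading (no centering), robustly scaled by the median z^2
        scale = np.median(zz**2) / CHI2_MEDIAN_1DF
        d2_poly = (zz**2 / scale).ravel()
    else:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(support_fraction=mcd_support, random_state=seed).fit(zz)
        d2_poly = mcd.mahalanobis(zz)
    d2 = np.zeros(g.n_loci)
    d2[poly] = d2_poly
    gif = float(np.median(d2_poly) / stats.chi2.ppf(0.5, k))
    p = stats.chi2.sf(d2 / gif, k)
    p[~poly] = 1.0
    q, _ = bh_fdr(p, q_threshold)
    ids = g.locus_ids
    stat = pd.DataFrame({"pcadapt": d2}, index=ids)
    return AssociationResult(
        effect=stat,
        z=pd.DataFrame({"pcadapt": np.sqrt(d2)}, index=ids),
        p=pd.DataFrame({"pcadapt": p}, index=ids),
        q=pd.DataFrame({"pcadapt": q}, index=ids),
        gif=pd.Series({"pcadapt": gif}),
        k=k,
        n_runs=1,
    )


def _multi_regression_z(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each locus on the full design; z for every design column."""
    n, p = design.shape
    xtx_inv = np.linalg.pinv(design.T @ design)
    coef = xtx_inv @ (design.T @ y)  # (p, L)
    resid = y - design @ coef
    df = max(n - p - 1, 1)
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(np.diag(xtx_inv)[:, None] * sigma2[None, :], 1e-300))
    return coef.T, (coef / se).T


def scree_elbow(explained: np.ndarray) -> int:
    """Suggest K at the elbow of an explained-variance scree (largest
    drop in successive differences); advisory only, never auto-applied."""
    e = np.asarray(explained, dtype=float)
    if e.size < 3:
        return 1
    second_diff = np.diff(e, 2)
    return int(np.argmax(second_diff) + 1)


# ----------------------------------------------------------- intersection


def intersect_outliers(
    gea: AssociationResult, fst_sets: list[OutlierSet], q_threshold: float = 0.10
) -> OutlierSet:
    """Putative adaptive loci: significant in the GEA scan (any variable)
    AND present in the union of differentiation-outlier sets."""
    gea_hits = gea.significant(q_threshold)
    union: set[str] = set()
    for s in fst_sets:
        union |= set(s.ids)
    gea_space = set(gea.q.index)
    if fst_sets and union and not (union & gea_space):
        raise ValueError("outlier sets share no locus ids with the GEA scan")
    ids = [lid for lid in gea_hits.ids if lid in union]
    prov = {}
    for lid in ids:
        methods = [s.method for s in fst_sets if lid in s.ids]
        prov[lid] = gea_hits.provenance.get(lid, []) + methods
    return OutlierSet(ids, "intersection", {"q_threshold": q_threshold}, prov)
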