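"""Population structure and diversity statistics.

Implements the estimators this kind of study leans on: Weir–Cockerham
(1984) theta with per-locus variance components and ratio-of-sums
multilocus/pairwise estimates, Weir–Goudet population-specific beta,
genotype PCA with per-locus mean imputation, Nei (1972) standard
distance, Saitou–Nei neighbor joining, PERMANOVA on an arbitrary
distance matrix, and hypergeometric projection of the folded site
frequency spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distmat import DistanceMatrix
from .genotypes import MISSING, GenotypeMatrix


class DegenerateInputError(ValueError):
    pass


# ----------------------------------------------------------------- F_ST


@dataclass
class FstResult:
    per_locus: pd.Series
    multilocus: float  # ratio of sums: sum(a) / sum(a+b+c)
    mean_of_ratios: float  # average of per-locus estimates
    pairwise: pd.DataFrame
    population_specific: pd.Series
    n_loci_skipped: int
    components: pd.DataFrame = field(repr=False)  # per-locus a, b, c

    def pairwise_linearized(self) -> DistanceMatrix:
        """F/(1-F) per pair, negatives clipped to 0, as a genetic DistanceMatrix."""
        vals = self.pairwise.to_numpy(float)
        lin = np.clip(vals, 0.0, None)
        lin = lin / (1.0 - lin)
        np.fill_diagonal(lin, 0.0)
        return DistanceMatrix(list(self.pairwise.index.astype(str)), (lin + lin.T) / 2.0, "genetic")


def _wc_components(counts_n: np.ndarray, counts_alt: np.ndarray, counts_het: np.ndarray):
    """Per-locus Weir–Cockerham variance components.

    Inputs are (n_pops, n_loci) arrays: genotyped diploids, alt-allele
    count over alleles, heterozygote count. Returns (a, b, c) with NaN
    where the locus is undefined (fewer than 2 populations with data,
    or average sample size of 1).
    """
    n = counts_n.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts_alt / (2.0 * n)
        h = counts_het / n
    present = n > 0
    r = present.sum(axis=0).astype(float)
    n_sum = np.where(present, n, 0.0).sum(axis=0)
    valid = r >= 2
    nbar = n_sum / np.maximum(r, 1.0)
    n2_sum = np.where(present, n**2, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_sum - n2_sum / n_sum) / (r - 1.0)
        pbar = np.where(present, n * p, 0.0).sum(axis=0) / n_sum
        s2 = np.where(present, n * (p - pbar) ** 2, 0.0).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = np.where(present, n * h, 0.0).sum(axis=0) / n_sum
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    valid &= nbar > 1.0
    valid &= nc > 0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def _pop_counts(g: GenotypeMatrix, pop_idx: dict[str, np.ndarray]):
    """Per-population genotyped-sample, alt-allele and heterozygote counts."""
    n_pops = len(pop_idx)
    n = np.zeros((n_pops, g.n_loci), dtype=int)
    alt = np.zeros_like(n)
    het = np.zeros_like(n)
    for i, idx in enumerate(pop_idx.values()):
        gg = g.genotypes[idx]
        called = gg != MISSING
        n[i] = called.sum(axis=0)
        alt[i] = np.where(called, gg, 0).sum(axis=0)
        het[i] = (gg == 1).sum(axis=0)
    return n, alt, het


def weir_cockerham_fst(g: GenotypeMatrix, grouping: list[str] | None = None) -> FstResult:
    """Weir–Cockerham (1984) theta across populations (or any grouping).

    The multilocus estimate is ratio-of-sums over loci with defined
    components; the per-locus average is also reported. Pairwise
    entries re-derive the components from each population pair alone.
    Population-specific values use the Weir–Goudet allele-matching
    beta, again as a ratio of sums over loci.
    """
    pops = list(grouping) if grouping is not None else list(g.populations)
    if len(pops) != g.n_individuals:
        raise ValueError("grouping length does not match individuals")
    arr = np.asarray(pops)
    names = list(dict.fromkeys(pops))
    if len(names) < 2:
        raise DegenerateInputError("need at least 2 populations")
    pop_idx = {p: np.flatnonzero(arr == p) for p in names}

    n, alt, het = _pop_counts(g, pop_idx)
    a, b, c = _wc_components(n, alt, het)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / denom
    defined = ~np.isnan(a) & (denom != 0)
    n_skipped = int(g.n_loci - defined.sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} loci had undefined F_ST components and were skipped")
    if not defined.any():
        raise DegenerateInputError("no locus with defined F_ST components")
    multilocus = float(np.nansum(np.where(defined, a, 0.0)) / np.nansum(np.where(defined, denom, 0.0)))
    mean_of_ratios = float(np.nanmean(np.where(defined, per_locus, np.nan)))

    pw = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            sel = np.ix_([i, j], np.arange(g.n_loci))
            ai, bi, ci = _wc_components(n[sel[0]], alt[sel[0]], het[sel[0]])
            di = ai + bi + ci
            ok = ~np.isnan(ai) & (di != 0)
            pw[i, j] = pw[j, i] = (
                float(np.nansum(np.where(ok, ai, 0.0)) / np.nansum(np.where(ok, di, 0.0)))
                if ok.any()
                else np.nan
            )

    beta = _weir_goudet_beta(n, alt, names)
    return FstResult(
        per_locus=pd.Series(per_locus, index=g.locus_ids),
        multilocus=multilocus,
        mean_of_ratios=mean_of_ratios,
        pairwise=pd.DataFrame(pw, index=names, columns=names),
        population_specific=beta,
        n_loci_skipped=n_skipped,
        components=pd.DataFrame({"a": a, "b": b, "c": c}, index=g.locus_ids),
    )


def _weir_goudet_beta(n: np.ndarray, alt: np.ndarray, names: list[str]) -> pd.Series:
    """Population-specific beta from allele-matching proportions."""
    m = 2.0 * n  # allele counts
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / m
        within = (alt * (alt - 1.0) + (m - alt) * (m - alt - 1.0)) / (m * (m - 1.0))
    n_pops = len(names)
    between = np.zeros(alt.shape[1])
    pair_ok = np.zeros(alt.shape[1])
    for i in range(n_pops):
        for j in range(i + 1, n_pops):
            ok = (n[i] > 0) & (n[j] > 0)
            mij = p[i] * p[j] + (1.0 - p[i]) * (1.0 - p[j])
            between = np.where(ok, between + mij, between)
            pair_ok = pair_ok + ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mb = between / pair_ok
    vals = {}
    for i, name in enumerate(names):
        ok = (n[i] > 1) & (pair_ok > 0) & ~np.isnan(within[i]) & ~np.isnan(mb)
        num = np.where(ok, within[i] - mb, 0.0).sum()
        den = np.where(ok, 1.0 - mb, 0.0).sum()
        vals[name] = num / den if den > 0 else np.nan
    return pd.Series(vals)


def linearized_fst(f: float) -> float:
    """Rousset's linearization F/(1-F); negative inputs pass through."""
    if f >= 1.0:
        raise ValueError("F_ST must be < 1 for linearization")
    if f < 0:
        warnings.warn("negative F_ST passed to linearization")
    return f / (1.0 - f)


# ------------------------------------------------------------------ PCA


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_ind, k)
    loadings: np.ndarray  # (n_loci, k)
    explained: np.ndarray  # variance fractions, non-increasing


def genotype_pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the mean-imputed, column-centered genotype matrix via SVD.

    Missing genotypes are replaced by the per-locus mean before
    centering; monomorphic columns are zero after centering and
    contribute nothing.
    """
    x = g.imputed()
    x = x - x.mean(axis=0)
    total = (x**2).sum()
    if total == 0.0:
        raise DegenerateInputError("all loci monomorphic after imputation")
    k = min(n_components, min(x.shape) - 1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    return PcaResult(
        scores=u[:, :k] * s[:k],
        loadings=vt[:k].T,
        explained=(s[:k] ** 2) / total,
    )


# ------------------------------------------------------- Nei distance, NJ

NEI_CAP = 30.0


def nei_distance(pop_freqs: pd.DataFrame) -> DistanceMatrix:
    """Nei (1972) standard genetic distance from biallelic frequencies.

    ``pop_freqs`` is populations x loci alt-allele frequency; NaN marks
    a population with no data at a locus, and each pair uses only its
    shared loci. D = -ln(J_xy / sqrt(J_x J_y)); pairs with J_xy = 0 are
    capped at 30 and the matrix flagged.
    """
    p = pop_freqs.to_numpy(float)
    names = [str(i) for i in pop_freqs.index]
    n = len(names)
    d = np.zeros((n, n))
    flagged = False
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(p[i]) & ~np.isnan(p[j])
            if not ok.any():
                raise DegenerateInputError(f"no shared loci between {names[i]} and {names[j]}")
            pi, pj = p[i, ok], p[j, ok]
            jx = np.mean(pi**2 + (1 - pi) ** 2)
            jy = np.mean(pj**2 + (1 - pj) ** 2)
            jxy = np.mean(pi * pj + (1 - pi) * (1 - pj))
            if jxy <= 0.0:
                d[i, j] = d[j, i] = NEI_CAP
                flagged = True
            else:
                d[i, j] = d[j, i] = min(-np.log(jxy / np.sqrt(jx * jy)), NEI_CAP)
    return DistanceMatrix(names, d, "genetic", flagged=flagged)


def frequency_distance(g: GenotypeMatrix, loci: list[str] | None = None) -> DistanceMatrix:
    """Mean absolute allele-frequency difference between populations.

    A bounded [0, 1] genetic dissimilarity (the L1 distance of the
    population frequency vectors divided by the locus count, over loci
    called in both populations). Unlike pairwise F_ST it does not
    saturate under strong drift, which makes it the better response for
    dissimilarity models that must localize turnover along a gradient.
    """
    pf = g.population_frequencies()
    if loci is not None:
        pf = pf[loci]
    p = pf.to_numpy(float)
    names = [str(i) for i in pf.index]
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(p[i]) & ~np.isnan(p[j])
            if not ok.any():
                raise DegenerateInputError(f"no shared loci between {names[i]} and {names[j]}")
            d[i, j] = d[j, i] = float(np.abs(p[i, ok] - p[j, ok]).mean())
    return DistanceMatrix(names, d, "genetic")


def neighbor_joining(d: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns a Newick string.

    Ties in the Q matrix break to the lexicographically lowest taxon
    index pair. Negative branch lengths are clamped to 0 with the
    deficit moved to the sibling branch.
    """
    if d.n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.isfinite(d.values).all():
        raise ValueError("distances must be finite")
    mat = d.values.copy()
    nodes = [f"{lab}" for lab in d.labels]
    active = list(range(d.n))
    newick = {i: nodes[i] for i in active}

    while len(active) > 3:
        m = len(active)
        sub = mat[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major => lowest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = sub[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = sub[i, j] - li
        if li < 0.0:
            lj += -li
            li = 0.0
        if lj < 0.0:
            li += -lj
            lj = 0.0
        ai, aj = active[i], active[j]
        new = mat.shape[0]
        newrow = np.zeros(new + 1)
        grown = np.zeros((new + 1, new + 1))
        grown[:new, :new] = mat
        for k_pos, ak in enumerate(active):
            if ak in (ai, aj):
                continue
            dist = (sub[i, k_pos] + sub[j, k_pos] - sub[i, j]) / 2.0
            grown[new, ak] = grown[ak, new] = max(dist, 0.0)
        mat = grown
        newick[new] = f"({newick[ai]}:{li:.10g},{newick[aj]}:{lj:.10g})"
        active = [a for a in active if a not in (ai, aj)] + [new]

    a, b, c = active
    dab, dac, dbc = mat[a, b], mat[a, c], mat[b, c]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"


# ------------------------------------------------------------ PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for gidx in range(n_groups):
        members = np.flatnonzero(codes == gidx)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d: DistanceMatrix, groups: list[str], n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F from the sum-of-squares partition of
    the squared distances, p by permuting group labels."""
    if len(groups) != d.n:
        raise ValueError("group labels do not match matrix")
    codes, counts = pd.factorize(np.asarray(groups))[0], None
    n_groups = codes.max() + 1
    sizes = np.bincount(codes)
    if n_groups < 2:
        raise DegenerateInputError("need at least 2 groups")
    if (sizes < 2).any():
        raise DegenerateInputError("every group needs at least 2 members")
    d2 = d.values**2
    obs = _permanova_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, n_groups) >= obs:
            count += 1
    return PermanovaResult(obs, (1 + count) / (1 + n_perm), n_perm)


# --------------------------------------------------------- SFS projection


@dataclass
class SfsResult:
    folded: np.ndarray  # index = minor-allele count 1..floor(m/2); [0] unused
    monomorphic_mass: float
    n_projected: int

    @property
    def polymorphic_mass(self) -> float:
        return float(self.folded.sum())


def project_sfs(allele_counts: np.ndarray, sample_sizes: np.ndarray, n_projected: int) -> SfsResult:
    """Project the folded SFS down to ``n_projected`` chromosomes.

    Each locus with derived count d of n chromosomes contributes the
    hypergeometric weights P(k | n, d, m) over k = 0..m; k = 0 and
    k = m accumulate as monomorphic-after-projection mass, interior k
    folds onto min(k, m - k). Total mass equals the locus count.
    """
    if n_projected < 2:
        raise ValueError("n_projected must be >= 2")
    counts = np.asarray(allele_counts, dtype=int)
    sizes = np.asarray(sample_sizes, dtype=int)
    if (sizes < n_projected).any():
        raise ValueError("n_projected exceeds an attainable sample size")
    m = n_projected
    folded = np.zeros(m // 2 + 1)
    mono = 0.0
    for d_count, n_chr in zip(counts, sizes):
        k = np.arange(m + 1)
        w = stats.hypergeom.pmf(k, n_chr, d_count, m)
        mono += w[0] + w[m]
        for kk in range(1, m):
            folded[min(kk, m - kk)] += w[kk]
    return SfsResult(folded, float(mono), m)


def sfs_input_from_genotypes(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele counts and chromosome counts per locus, over called genotypes."""
    called = g.genotypes != MISSING
    alt = np.where(called, g.genotypes, 0).sum(axis=0)
    return alt, 2 * called.sum(axis=0)


def raw_folded_sfs(g: GenotypeMatrix) -> np.ndarray:
    """Folded SFS at the full (uniform) sample size; requires no missing data."""
    alt, chroms = sfs_input_from_genotypes(g)
    if len(set(chroms.tolist())) != 1:
        raise ValueError("raw SFS needs a uniform sample size (no missing data)")
    m = int(chroms[0])
    folded = np.zeros(m // 2 + 1)
    for a in alt:
        f = min(int(a), m - int(a))
        if f > 0:
            folded[f] += 1
    return folded
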