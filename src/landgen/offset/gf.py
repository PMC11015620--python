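"""Gradient-forest turnover modeling and offset.

Each adaptive locus is fitted with a random-forest regression of
allele dosage on the environmental variables. Impurity reductions at
every split are pooled along each variable's range, weighted by the
locus out-of-bag R^2, and accumulated into monotone cumulative-
importance turnover functions that map climate into a common "genetic
composition" space. The offset between two scenarios is the Euclidean
distance between a cell's transformed vectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..envtable import EnvTable
from ..genotypes import GenotypeMatrix
from ..grids import ClimateGrid


@dataclass
class TurnoverFunction:
    """Non-decreasing step function: 0 below the first split, rising by
    the pooled importance at each split position."""

    positions: np.ndarray  # sorted split thresholds
    cumulative: np.ndarray  # cumulative importance after each position

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if len(self.positions) == 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        idx = np.searchsorted(self.positions, np.asarray(x, dtype=float), side="right")
        cum = np.concatenate([[0.0], self.cumulative])
        return cum[idx]

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0


@dataclass
class GFModel:
    variables: list[str]
    turnover: dict[str, TurnoverFunction]
    importance: pd.Series  # per-variable share of total weighted R^2
    locus_r2: pd.Series  # out-of-bag R^2 of retained loci
    n_trees: int
    max_depth: int
    corr_threshold: float = 0.5  # recorded band-width correlation parameter

    def transform(self, env: np.ndarray) -> np.ndarray:
        """Map environment rows (n, n_var) into genetic-composition space."""
        env = np.atleast_2d(np.asarray(env, dtype=float))
        return np.column_stack([self.turnover[v](env[:, i]) for i, v in enumerate(self.variables)])


def gf_fit(
    g_adaptive: GenotypeMatrix,
    env: EnvTable,
    n_trees: int = 500,
    seed: int = 0,
    r2_floor: float = 0.0,
    corr_threshold: float = 0.5,
) -> GFModel:
    """Fit per-locus random forests and pool split importance.

    The split-depth cap is ceil(log2(0.368 * n / 2)) with n the number
    of rows (individuals), the standard heuristic for conditioning
    forests on modest sample sizes. Loci whose out-of-bag R^2 does not
    exceed ``r2_floor`` carry no weight and are dropped.
    """
    from sklearn.ensemble import RandomForestRegressor

    if g_adaptive.n_loci < 2:
        raise ValueError("need at least 2 adaptive loci")
    if env.n_sites != g_adaptive.n_individuals:
        raise ValueError("env rows must align with individuals")
    x = env.values()
    variables = env.variables
    n = g_adaptive.n_individuals
    max_depth = max(1, math.ceil(math.log2(max(0.368 * n / 2.0, 2.0))))
    y_all = g_adaptive.imputed()

    kept_r2: dict[str, float] = {}
    # per variable: lists of split positions and their weighted importances
    splits: dict[str, list[np.ndarray]] = {v: [] for v in variables}
    gains: dict[str, list[np.ndarray]] = {v: [] for v in variables}

    for j, lid in enumerate(g_adaptive.locus_ids):
        y = y_all[:, j]
        if y.std() == 0.0:
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_depth=max_depth,
            oob_score=True,
            bootstrap=True,
            random_state=seed + j,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # OOB warning on tiny samples
            rf.fit(x, y)
        r2 = float(rf.oob_score_)
        if not np.isfinite(r2) or r2 <= r2_floor:
            continue
        kept_r2[lid] = r2
        pos, gain = _forest_split_gains(rf, len(variables))
        total_gain = sum(g.sum() for g in gain.values())
        if total_gain <= 0:
            continue
        for vi, v in enumerate(variables):
            if len(pos[vi]):
                splits[v].append(pos[vi])
                # locus contributes its R^2, distributed over its splits
                gains[v].append(gain[vi] * (r2 / total_gain))

    if not kept_r2:
        raise RuntimeError("no predictive loci: every locus fell below the R^2 floor")

    turnover: dict[str, TurnoverFunction] = {}
    raw_totals = {}
    for v in variables:
        if splits[v]:
            p = np.concatenate(splits[v])
            w = np.concatenate(gains[v])
            order = np.argsort(p, kind="stable")
            p, w = p[order], w[order]
            turnover[v] = TurnoverFunction(p, np.cumsum(w))
        else:
            turnover[v] = TurnoverFunction(np.array([]), np.array([]))
        raw_totals[v] = turnover[v].total
    total = sum(raw_totals.values())
    importance = pd.Series({v: raw_totals[v] / total for v in variables})
    return GFModel(
        variables=list(variables),
        turnover=turnover,
        importance=importance,
        locus_r2=pd.Series(kept_r2),
        n_trees=n_trees,
        max_depth=max_depth,
        corr_threshold=corr_threshold,
    )


def _forest_split_gains(rf, n_var: int):
    """Split positions and impurity reductions per variable, pooled over
    all trees of a fitted forest."""
    pos: dict[int, list[float]] = {v: [] for v in range(n_var)}
    gain: dict[int, list[float]] = {v: [] for v in range(n_var)}
    for est in rf.estimators_:
        t = est.tree_
        for node in range(t.node_count):
            f = t.feature[node]
            if f < 0:  # leaf
                continue
            left, right = t.children_left[node], t.children_right[node]
            dec = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            )
            if dec > 0:
                pos[f].append(float(t.threshold[node]))
                gain[f].append(float(dec))
    return (
        {v: np.asarray(pos[v]) for v in range(n_var)},
        {v: np.asarray(gain[v]) for v in range(n_var)},
    )


def gf_offset(model: GFModel, current: ClimateGrid, future: ClimateGrid) -> np.ndarray:
    """Per-cell offset: Euclidean distance between the transformed
    current and future environment vectors (NaN where masked)."""
    _check_grids(model, current, future)
    idx = current.unmasked_indices()
    t_cur = model.transform(current.env_at_cells(idx))
    t_fut = model.transform(future.env_at_cells(idx))
    d = np.sqrt(((t_cur - t_fut) ** 2).sum(axis=1))
    out = np.full(current.shape, np.nan)
    out.ravel()[idx] = d
    return out


def gf_rgb_map(model: GFModel, grid: ClimateGrid) -> np.ndarray:
    """First three PCs of the transformed cell vectors as RGB channels
    scaled to [0, 1]; fewer than 3 effective dimensions pad with zeros."""
    idx = grid.unmasked_indices()
    t = model.transform(grid.env_at_cells(idx))
    tc = t - t.mean(axis=0)
    u, s, _ = np.linalg.svd(tc, full_matrices=False)
    n_eff = int((s > max(s[0], 1e-30) * 1e-9).sum()) if len(s) else 0
    if n_eff < 3:
        warnings.warn(f"only {n_eff} effective dimensions; padding RGB with zero channels")
    scores = u[:, :3] * s[:3] if t.shape[1] >= 3 else np.pad(u * s, ((0, 0), (0, 3 - t.shape[1])))
    out = np.full(grid.shape + (3,), np.nan)
    for ch in range(3):
        col = scores[:, ch] if ch < scores.shape[1] and ch < n_eff else np.zeros(len(idx))
        lo, hi = col.min(), col.max()
        span = hi - lo if hi > lo else 1.0
        plane = np.full(grid.shape, np.nan)
        plane.ravel()[idx] = (col - lo) / span
        out[..., ch] = plane
    return out


def _check_grids(model: GFModel, current: ClimateGrid, future: ClimateGrid) -> None:
    if current.variables != model.variables or future.variables != model.variables:
        raise ValueError("grid variables do not match the fitted model")
    if current.shape != future.shape or not np.array_equal(current.mask, future.mask):
        raise ValueError("current and future grids must share shape and mask")
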