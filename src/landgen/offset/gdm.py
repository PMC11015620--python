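"""Generalized dissimilarity modeling and local/forward/reverse offsets.

GDM regresses pairwise genetic dissimilarity d_ij in [0, 1) on
monotone I-spline transforms of the site environmental values (and
optionally great-circle geographic distance) through the link
d = 1 - exp(-eta), eta = beta0 + sum_k sum_s beta_ks
|I_ks(x_ik) - I_ks(x_jk)|, all coefficients nonnegative. Fitting is
iteratively reweighted non-negative least squares on the
complementary-log working response.

Offsets between two climates drop the intercept and the geographic
term: the predicted dissimilarity attributable to environmental
separation alone, so identical environments give exactly zero and the
forward/reverse minimization encodes no dispersal penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls
from scipy.spatial.distance import cdist

from ..distmat import DistanceMatrix
from ..envtable import EnvTable
from ..grids import ClimateGrid, haversine_km, initial_bearing_deg
from .surfaces import OffsetSurface

_DEGREE = 2


def ispline_basis(x: np.ndarray, knots: np.ndarray, n_splines: int = 3) -> np.ndarray:
    """Monotone I-spline basis (n points x n_splines), each column
    non-decreasing from 0 at the first knot to 1 at the last.

    ``knots`` are the n_splines - 1 quantile knots plus the endpoints:
    [min, interior..., max]. Inputs outside the range are clamped.
    """
    knots = np.asarray(knots, dtype=float)
    mn, mx = knots[0], knots[-1]
    x = np.clip(np.asarray(x, dtype=float), mn, mx)
    if mx <= mn:
        return np.zeros((len(x), n_splines))
    t = np.concatenate([[mn] * (_DEGREE + 1), knots[1:-1], [mx] * (_DEGREE + 1)])
    n_b = len(t) - _DEGREE - 1  # = n_splines + 1
    dm = BSpline.design_matrix(x, t, _DEGREE, extrapolate=False).toarray()
    # cumulative sum of B-splines from the right gives I-splines
    rev = np.cumsum(dm[:, ::-1], axis=1)[:, ::-1]
    return rev[:, 1:n_b]


def _quantile_knots(values: np.ndarray, n_splines: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, n_splines)
    return np.quantile(np.asarray(values, dtype=float), qs)


@dataclass
class GDMModel:
    intercept: float
    predictors: list[str]  # env variables, plus "geographic" if used
    knots: dict[str, np.ndarray]
    coefs: dict[str, np.ndarray]  # nonnegative, length n_splines
    n_splines: int
    deviance_explained: float
    y_scale: float = 1.0  # factor applied to rescale dissimilarities below 1
    trace: list[float] = field(default_factory=list, repr=False)

    @property
    def env_predictors(self) -> list[str]:
        return [p for p in self.predictors if p != "geographic"]

    def transform_env(self, env: np.ndarray) -> np.ndarray:
        """Coefficient-weighted I-spline features of environment rows;
        the L1 distance between two transformed rows is the spline part
        of eta between the two environments."""
        env = np.atleast_2d(np.asarray(env, dtype=float))
        cols = []
        for i, var in enumerate(self.env_predictors):
            basis = ispline_basis(env[:, i], self.knots[var], self.n_splines)
            cols.append(basis * self.coefs[var][None, :])
        return np.hstack(cols)


def gdm_fit(
    gen_dissim: DistanceMatrix,
    env: EnvTable,
    coords: pd.DataFrame | None = None,
    n_splines: int = 3,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GDMModel:
    """Fit a GDM to pairwise genetic dissimilarities.

    ``env`` holds the site values (rows aligned with the matrix
    labels); ``coords`` (lat/lon per site) adds great-circle distance
    as a predictor with I-splines on the pairwise distances, or None to
    omit it. Dissimilarities above 1 are rescaled into [0, 1) and the
    factor recorded. Raises on negative dissimilarities or
    non-convergence.
    """
    if gen_dissim.n < 6:
        raise ValueError("need at least 6 sites to fit a GDM")
    if env.sites != gen_dissim.labels:
        raise ValueError("env table must be aligned with the dissimilarity labels")
    y = gen_dissim.condensed().astype(float)
    if (y < 0).any():
        raise ValueError("negative dissimilarities")
    y_scale = 1.0
    if y.max() >= 1.0:
        y_scale = 0.999 / y.max()
        y = y * y_scale

    iu = np.triu_indices(gen_dissim.n, 1)
    x_env = env.values()
    predictors = list(env.variables)
    knots = {v: _quantile_knots(x_env[:, i], n_splines) for i, v in enumerate(predictors)}
    design_cols = []
    for i, var in enumerate(predictors):
        basis = ispline_basis(x_env[:, i], knots[var], n_splines)  # per site
        design_cols.append(np.abs(basis[iu[0]] - basis[iu[1]]))
    if coords is not None:
        lat = coords["lat"].to_numpy(float)
        lon = coords["lon"].to_numpy(float)
        dmat = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        dpair = dmat[iu]
        gk = _quantile_knots(dpair, n_splines)
        knots["geographic"] = gk
        design_cols.append(ispline_basis(dpair, gk, n_splines))
        predictors.append("geographic")

    x = np.hstack([np.ones((len(y), 1))] + design_cols)
    beta, dev, trace = _irls_nnls(x, y, max_iter, tol)
    null_beta, null_dev, _ = _irls_nnls(np.ones((len(y), 1)), y, max_iter, tol)
    dev_explained = 1.0 - dev / null_dev if null_dev > 0 else np.nan

    coefs = {}
    for i, var in enumerate(predictors):
        coefs[var] = beta[1 + i * n_splines : 1 + (i + 1) * n_splines]
    return GDMModel(
        intercept=float(beta[0]),
        predictors=predictors,
        knots=knots,
        coefs=coefs,
        n_splines=n_splines,
        deviance_explained=float(dev_explained),
        y_scale=y_scale,
        trace=trace,
    )


def _irls_nnls(x: np.ndarray, y: np.ndarray, max_iter: int, tol: float):
    """IRLS with an NNLS inner solve for the 1 - exp(-eta) link and
    sum-of-squares deviance."""
    mu = np.clip(y, 1e-4, 1.0 - 1e-4)
    eta = -np.log(1.0 - mu)
    dev_prev = np.inf
    trace: list[float] = []
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        mu = 1.0 - np.exp(-eta)
        grad = 1.0 - mu  # d mu / d eta
        z = eta + (y - mu) / np.maximum(grad, 1e-10)
        w = np.sqrt(np.maximum(grad, 1e-10) ** 2)
        beta, _ = nnls(x * w[:, None], z * w)
        eta = x @ beta
        mu = 1.0 - np.exp(-eta)
        dev = float(((y - mu) ** 2).sum())
        trace.append(dev)
        if abs(dev_prev - dev) < tol:
            return beta, dev, trace
        dev_prev = dev
    raise RuntimeError(f"GDM IRLS did not converge in {max_iter} iterations; deviance trace: {trace[-5:]}")


def predict_dissimilarity(
    model: GDMModel, env_i: np.ndarray, env_j: np.ndarray, dist_km: float | np.ndarray = 0.0
) -> np.ndarray:
    """Full-model predicted dissimilarity between paired sites
    (intercept and geographic term included)."""
    ti = model.transform_env(env_i)
    tj = model.transform_env(env_j)
    eta = model.intercept + np.abs(ti - tj).sum(axis=1)
    if "geographic" in model.predictors:
        basis = ispline_basis(np.atleast_1d(np.asarray(dist_km, float)), model.knots["geographic"], model.n_splines)
        eta = eta + basis @ model.coefs["geographic"]
    return 1.0 - np.exp(-eta)


def _env_offset(t_a: np.ndarray, t_b: np.ndarray) -> np.ndarray:
    """Offset between transformed env rows: 1 - exp(-L1 distance)."""
    return 1.0 - np.exp(-np.abs(t_a - t_b).sum(axis=1))


def gdm_offsets(
    model: GDMModel,
    current: ClimateGrid,
    future: ClimateGrid,
    candidate_mask: np.ndarray | None = None,
) -> OffsetSurface:
    """Local, forward and reverse offsets on the grid.

    local(i): offset between cell i's current and future environment.
    forward(i): minimum offset from current cell i to any candidate
    cell's future environment (default candidates: the future-suitable
    cells), with the great-circle distance and initial bearing to the
    argmin recorded. reverse(i): minimum offset from cell i's future
    environment to any current-suitable cell. Ties break by smallest
    distance, then lowest cell index.
    """
    if current.variables != model.env_predictors or future.variables != model.env_predictors:
        raise ValueError("grid variables do not match the fitted model")
    if current.shape != future.shape:
        raise ValueError("grids must share shape")
    if not current.mask.any():
        raise ValueError("empty suitability mask")

    focal_idx = current.unmasked_indices()
    cand_mask = future.mask if candidate_mask is None else np.asarray(candidate_mask, bool)
    cand_idx = np.flatnonzero(cand_mask.ravel())
    if len(cand_idx) == 0:
        raise ValueError("empty candidate mask")

    t_cur = model.transform_env(current.env_at_cells(focal_idx))
    t_fut_focal = model.transform_env(future.env_at_cells(focal_idx))
    t_fut_cand = model.transform_env(future.env_at_cells(cand_idx))
    t_cur_cand = model.transform_env(current.env_at_cells(cand_idx))

    ncols = current.shape[1]
    lat_f, lon_f = current.cell_coords(focal_idx // ncols, focal_idx % ncols)
    lat_c, lon_c = current.cell_coords(cand_idx // ncols, cand_idx % ncols)

    local = _env_offset(t_cur, t_fut_focal)

    eta_fwd = cdist(t_cur, t_fut_cand, metric="cityblock")
    fwd = 1.0 - np.exp(-eta_fwd)
    forward = np.empty(len(focal_idx))
    target = np.empty(len(focal_idx), dtype=int)
    dist = np.empty(len(focal_idx))
    bear = np.empty(len(focal_idx))
    for r in range(len(focal_idx)):
        row = fwd[r]
        m = row.min()
        ties = np.flatnonzero(row <= m + 1e-12)
        dd = haversine_km(lat_f[r], lon_f[r], lat_c[ties], lon_c[ties])
        best = ties[np.lexsort((cand_idx[ties], np.round(dd, 9)))[0]]
        forward[r] = row[best]
        target[r] = cand_idx[best]
        if target[r] == focal_idx[r]:
            dist[r], bear[r] = 0.0, 0.0
        else:
            t_lat, t_lon = current.cell_coords(target[r] // ncols, target[r] % ncols)
            dist[r] = haversine_km(lat_f[r], lon_f[r], t_lat, t_lon)
            bear[r] = initial_bearing_deg(lat_f[r], lon_f[r], t_lat, t_lon)

    eta_rev = cdist(t_fut_focal, t_cur_cand, metric="cityblock")
    reverse = (1.0 - np.exp(-eta_rev)).min(axis=1)

    def to_grid(vals, fill=np.nan, dtype=float):
        out = np.full(current.shape, fill, dtype=dtype)
        out.ravel()[focal_idx] = vals
        return out

    return OffsetSurface(
        grid=current,
        local=to_grid(local),
        forward=to_grid(forward),
        reverse=to_grid(reverse),
        forward_target=to_grid(target, fill=-1, dtype=int),
        distance_km=to_grid(dist),
        bearing_deg=to_grid(bear),
        scenario=future.scenario,
    )
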