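"""Synthetic landscape-genomics scenarios with recorded ground truth.

The generator emulates a reduced-representation SNP study of ~26
populations of ~8 trees sampled along climatic gradients: spatially
autocorrelated environmental layers, hierarchical drift calibrated to a
target multilocus F_ST via the Balding–Nichols model, a small fraction
of loci carrying logistic allele-frequency clines on one or more
environmental variables, ~11% missing genotypes, and a future scenario
equal to the current one plus per-variable shifts. Every stochastic
choice is recorded in a :class:`GroundTruth` so that parameter-recovery
tests (F_ST calibration, GEA power/FDR, offset accuracy) can score the
pipeline against known truth.

The drift model draws population allele frequencies independently per
population around an ancestral frequency; it deliberately omits linkage
disequilibrium, shared demographic history and selection through time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .envtable import EnvTable
from .genotypes import MISSING, GenotypeMatrix, Locus, write_samples_csv, write_vcf
from .grids import ClimateGrid


class ParameterError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass
class SimulationConfig:
    """Scenario description; defaults emulate the study design.

    ``beta`` is the per-adaptive-locus cline slope on the logit scale
    (scalar = shared by all adaptive loci). ``future_delta`` is the
    additive shift per environmental variable, in units of the
    standardized layers (scalar = applied to the first variable only).
    ``n_driver_vars`` cycles adaptive loci over the first k variables.
    """

    grid_rows: int = 40
    grid_cols: int = 40
    n_env: int = 5
    autocorr_range: float = 6.0
    n_pops: int = 26
    n_ind_per_pop: int = 8
    n_neutral: int = 1000
    n_adaptive: int = 50
    fst_target: float = 0.10
    beta: float | np.ndarray = 1.5
    missing_rate: float = 0.11
    future_delta: float | np.ndarray = 1.0
    n_driver_vars: int = 1
    mask_fraction: float = 0.0
    jitter_cells: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("grid_rows", "grid_cols", "n_env", "n_pops", "n_ind_per_pop", "n_neutral"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.n_adaptive < 0:
            raise ParameterError("n_adaptive must be >= 0")
        if self.autocorr_range <= 0:
            raise ParameterError("autocorr_range must be positive")
        if not 0.0 < self.fst_target < 1.0:
            raise ParameterError("fst_target must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.mask_fraction < 1.0:
            raise ParameterError("mask_fraction must be in [0, 1)")
        if self.n_driver_vars < 1 or self.n_driver_vars > self.n_env:
            raise ParameterError("n_driver_vars must be in [1, n_env]")

    def beta_vector(self) -> np.ndarray:
        b = np.broadcast_to(np.asarray(self.beta, dtype=float), (self.n_adaptive,))
        return np.array(b)

    def delta_vector(self) -> np.ndarray:
        d = np.asarray(self.future_delta, dtype=float)
        if d.ndim == 0:
            out = np.zeros(self.n_env)
            out[0] = float(d)
            return out
        if d.shape != (self.n_env,):
            raise ParameterError("future_delta must be scalar or length n_env")
        return d.copy()


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    adaptive_locus_ids: list[str]
    p0: dict[str, float]
    beta: dict[str, float]
    driver: dict[str, str]
    true_cell_offset: np.ndarray = field(repr=False)  # mean |Δp| per cell, masked = nan
    pop_cells: list[int] = field(default_factory=list)  # flat cell index per population

    def to_json(self, path: str | Path) -> None:
        payload = {
            "adaptive_locus_ids": self.adaptive_locus_ids,
            "p0": self.p0,
            "beta": self.beta,
            "driver": self.driver,
            "true_cell_offset": np.where(
                np.isnan(self.true_cell_offset), None, self.true_cell_offset
            ).tolist(),
            "pop_cells": self.pop_cells,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        offs = np.array(
            [[np.nan if v is None else v for v in row] for row in d["true_cell_offset"]], dtype=float
        )
        return cls(d["adaptive_locus_ids"], d["p0"], d["beta"], d["driver"], offs, d["pop_cells"])


# ------------------------------------------------------------- landscape


def _gaussian_random_field(rng: np.random.Generator, shape: tuple[int, int], corr: float) -> np.ndarray:
    """Kernel-convolution synthesis: white noise smoothed with a Gaussian
    kernel of sd ``corr`` cells (wrap-around boundary), standardized."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=corr, mode="wrap")
    return (f - f.mean()) / f.std()


def simulate_landscape(config: SimulationConfig) -> tuple[ClimateGrid, ClimateGrid]:
    """Generate current and future climate grids.

    Each layer is a Gaussian random field with correlation length
    ``autocorr_range`` cells, standardized to mean 0 / sd 1 over
    unmasked cells; the future grid adds ``future_delta`` per variable.
    Both scenarios share the suitability mask.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    names = [f"env{i + 1}" for i in range(config.n_env)]
    layers = np.stack(
        [_gaussian_random_field(rng, shape, config.autocorr_range) for _ in range(config.n_env)]
    )
    if config.mask_fraction > 0.0:
        suit = _gaussian_random_field(rng, shape, config.autocorr_range)
        thresh = np.quantile(suit, config.mask_fraction)
        mask = suit >= thresh
    else:
        mask = np.ones(shape, dtype=bool)
    # re-standardize over unmasked cells only
    for k in range(config.n_env):
        v = layers[k][mask]
        layers[k] = (layers[k] - v.mean()) / v.std()
    current = ClimateGrid(names, layers, mask=mask, scenario="current")
    future = current.copy(scenario="future")
    future.layers = future.layers + config.delta_vector()[:, None, None]
    return current, future


# ------------------------------------------------------------- genotypes


def _place_populations(config: SimulationConfig, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Deterministic lattice placement with seeded jitter; returns flat
    cell indices, one per population, all on unmasked cells."""
    nrows, ncols = mask.shape
    k = int(np.ceil(np.sqrt(config.n_pops)))
    rows = np.linspace(0, nrows - 1, k + 2)[1:-1]
    cols = np.linspace(0, ncols - 1, k + 2)[1:-1]
    lattice = [(r, c) for r in rows for c in cols][: config.n_pops]
    if len(lattice) < config.n_pops:
        raise ParameterError("grid too small for requested population count")
    unmasked = np.argwhere(mask)
    if len(unmasked) < config.n_pops:
        raise ParameterError("n_pops exceeds the number of unmasked cells")
    taken: set[int] = set()
    cells = []
    for r, c in lattice:
        jr = r + rng.integers(-config.jitter_cells, config.jitter_cells + 1)
        jc = c + rng.integers(-config.jitter_cells, config.jitter_cells + 1)
        # snap to nearest free unmasked cell
        d2 = (unmasked[:, 0] - jr) ** 2 + (unmasked[:, 1] - jc) ** 2
        for idx in np.argsort(d2, kind="stable"):
            flat = int(unmasked[idx, 0] * ncols + unmasked[idx, 1])
            if flat not in taken:
                taken.add(flat)
                cells.append(flat)
                break
    return np.array(cells)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


FREQ_CLIP = (0.001, 0.999)


def simulate_genotypes(
    config: SimulationConfig, climate: ClimateGrid
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw genotypes for populations placed on the landscape.

    Neutral loci follow the Balding–Nichols model: ancestral frequency
    p0 ~ U(0.05, 0.95) and population frequency ~ Beta with mean p0 and
    drift parameter F = ``fst_target``. Adaptive loci shift the drawn
    frequency on the logit scale by beta * z, z the driving variable's
    standardized value at the population's cell. Genotypes are
    Binomial(2, freq) with i.i.d. missingness at ``missing_rate``.
    Frequencies are clipped to [0.001, 0.999] before sampling;
    monomorphic realized loci are retained.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    cells = _place_populations(config, climate.mask, rng)
    n_pops, n_ind = config.n_pops, config.n_ind_per_pop
    n_loci = config.n_neutral + config.n_adaptive
    F = config.fst_target

    p0 = rng.uniform(0.05, 0.95, size=n_loci)
    a = p0 * (1.0 - F) / F
    b = (1.0 - p0) * (1.0 - F) / F
    pop_freq = rng.beta(a[None, :], b[None, :], size=(n_pops, n_loci))
    pop_freq = np.clip(pop_freq, *FREQ_CLIP)

    betas = config.beta_vector()
    drivers = np.arange(config.n_adaptive) % config.n_driver_vars
    env_at_pops = climate.env_at_cells(cells)  # (n_pops, n_env)
    adaptive_cols = np.arange(config.n_neutral, n_loci)
    for j, (col, bj, dv) in enumerate(zip(adaptive_cols, betas, drivers)):
        z = env_at_pops[:, dv]
        pop_freq[:, col] = _logistic(_logit(pop_freq[:, col]) + bj * z)
    pop_freq = np.clip(pop_freq, *FREQ_CLIP)

    geno = rng.binomial(2, np.repeat(pop_freq, n_ind, axis=0)).astype(np.int16)
    miss = rng.random(geno.shape) < config.missing_rate
    geno[miss] = MISSING

    loci = [Locus("chr1", 100 * (j + 1)) for j in range(n_loci)]
    ids = [f"p{i + 1:02d}_i{k + 1}" for i in range(n_pops) for k in range(n_ind)]
    pops = [f"p{i + 1:02d}" for i in range(n_pops) for _ in range(n_ind)]
    rows, colsg = np.divmod(np.repeat(cells, n_ind), climate.shape[1])
    lat, lon = climate.cell_coords(rows, colsg)

    truth = _ground_truth(config, climate, loci, p0, betas, drivers, cells)
    g = GenotypeMatrix(geno, loci, ids, pops, lat, lon, ground_truth=truth)
    return g, truth


def _ground_truth(
    config: SimulationConfig,
    climate: ClimateGrid,
    loci: list[Locus],
    p0: np.ndarray,
    betas: np.ndarray,
    drivers: np.ndarray,
    cells: np.ndarray,
) -> GroundTruth:
    """Per-cell expected |Δ allele frequency| under the future deltas,
    averaged over adaptive loci (the deterministic cline component)."""
    names = climate.variables
    delta = config.delta_vector()
    offs = np.full(climate.shape, np.nan)
    if config.n_adaptive:
        zcur = climate.layers  # (n_env, r, c)
        dp = np.zeros(climate.shape)
        for bj, dv, p in zip(betas, drivers, p0[config.n_neutral:]):
            eta = _logit(np.full(climate.shape, np.clip(p, *FREQ_CLIP)))
            pc = _logistic(eta + bj * zcur[dv])
            pf = _logistic(eta + bj * (zcur[dv] + delta[dv]))
            dp += np.abs(pf - pc)
        offs = np.where(climate.mask, dp / config.n_adaptive, np.nan)
    else:
        offs = np.where(climate.mask, 0.0, np.nan)
    adaptive_ids = [loci[j].id for j in range(config.n_neutral, len(loci))]
    return GroundTruth(
        adaptive_locus_ids=adaptive_ids,
        p0={l.id: float(p) for l, p in zip(loci, p0)},
        beta={l.id: 0.0 for l in loci[: config.n_neutral]}
        | {lid: float(b) for lid, b in zip(adaptive_ids, betas)},
        driver={lid: names[dv] for lid, dv in zip(adaptive_ids, drivers)},
        true_cell_offset=offs,
        pop_cells=[int(c) for c in cells],
    )


def population_env_table(g: GenotypeMatrix, climate: ClimateGrid, truth: GroundTruth) -> EnvTable:
    """Environment table at the population cells (populations x variables)."""
    env = climate.env_at_cells(np.asarray(truth.pop_cells))
    import pandas as pd

    df = pd.DataFrame(env, index=g.population_names(), columns=climate.variables)
    return EnvTable(df, {v: "climate" for v in climate.variables}, scaled=True)


def individual_env_table(g: GenotypeMatrix, climate: ClimateGrid, truth: GroundTruth) -> EnvTable:
    """Environment table aligned to individuals (repeats population rows)."""
    import pandas as pd

    pop_env = population_env_table(g, climate, truth)
    rows = pop_env.data.loc[g.populations].to_numpy()
    df = pd.DataFrame(rows, index=g.individual_ids, columns=climate.variables)
    return EnvTable(df, dict(pop_env.categories), scaled=True)


def write_scenario(
    directory: str | Path,
    g: GenotypeMatrix,
    truth: GroundTruth,
    current: ClimateGrid,
    future: ClimateGrid,
) -> dict[str, Path]:
    """Write the full scenario: VCF, samples CSV, env CSV, grids, truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "genotypes.vcf",
        "samples": directory / "samples.csv",
        "env": directory / "environment.csv",
        "truth": directory / "ground_truth.json",
    }
    write_vcf(g, paths["vcf"])
    write_samples_csv(g, paths["samples"])
    population_env_table(g, current, truth).to_csv(paths["env"])
    truth.to_json(paths["truth"])
    current.write_ascii(directory / "current")
    future.write_ascii(directory / "future")
    return paths


def simulate_scenario(
    config: SimulationConfig | None = None, **overrides
) -> tuple[GenotypeMatrix, GroundTruth, ClimateGrid, ClimateGrid]:
    """One-call scenario generation with config overrides."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    current, future = simulate_landscape(config)
    g, truth = simulate_genotypes(config, current)
    return g, truth, current, future
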