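"""End-to-end orchestration: filter -> structure -> scan -> models -> offset.

Each stage writes its artifacts plus a provenance sidecar (config
hash, seed, package version); a rerun skips stages whose provenance
matches the resolved configuration, so deleting one stage's outputs
recomputes only that stage and everything downstream of it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distmat import DistanceMatrix, build_distances
from .envtable import EnvTable
from .genotypes import GenotypeMatrix, filter_snps, read_vcf, write_samples_csv, write_vcf
from .grids import ClimateGrid, read_grid_stack
from .gea import bh_fdr, fit_lfmm, intersect_outliers, pcadapt_scan, OutlierSet
from .landscape import fully_supported, mantel, mlpe_fit, partial_mantel, pcnm, prune_collinear, rcm, rda_partition
from .popgen import (frequency_distance, genotype_pca, nei_distance, neighbor_joining, permanova,
                     project_sfs, sfs_input_from_genotypes, weir_cockerham_fst)
from .offset import gdm_fit, gdm_offsets, gf_fit, gf_offset, rona

log = logging.getLogger("landgen")

STAGES = ("simulate", "filter", "structure", "scan", "models", "offset")


@dataclass
class RunConfig:
    """Resolved run configuration; defaults follow standard practice for
    this analysis chain (hard filters missing<0.4 / MAF>0.01, FDR<10%,
    999 Mantel permutations, 100 equivalency permutations)."""

    outdir: str = "landgen_run"
    # inputs (ignored when simulate=True)
    vcf: str | None = None
    samples: str | None = None
    env_csv: str | None = None
    current_grids: dict[str, str] = field(default_factory=dict)
    future_grids: dict[str, str] = field(default_factory=dict)
    resistance: dict[str, str] = field(default_factory=dict)
    external_outliers: list[str] = field(default_factory=list)
    # synthetic scenario
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    # thresholds
    max_missing: float = 0.4
    min_maf: float = 0.01
    fdr_q: float = 0.10
    k_lfmm: int = 2
    lfmm_runs: int = 10
    k_pcadapt: int = 2
    mantel_permutations: int = 999
    equivalency_permutations: int = 100
    rda_permutations: int = 199
    gf_trees: int = 500
    seed: int = 0

    def resolved_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance_path(outdir: Path, stage: str) -> Path:
    return outdir / f".provenance_{stage}.json"


def _stage_done(cfg: RunConfig, outdir: Path, stage: str) -> bool:
    path = _provenance_path(outdir, stage)
    if not path.exists():
        return False
    try:
        prov = json.loads(path.read_text())
    except json.JSONDecodeError:
        return False
    return prov.get("config_hash") == cfg.resolved_hash()


def _mark_done(cfg: RunConfig, outdir: Path, stage: str, artifacts: list[str]) -> None:
    _provenance_path(outdir, stage).write_text(
        json.dumps(
            {
                "stage": stage,
                "config_hash": cfg.resolved_hash(),
                "seed": cfg.seed,
                "version": __version__,
                "artifacts": artifacts,
            },
            indent=1,
        )
    )


@dataclass
class PipelineState:
    genotypes: GenotypeMatrix | None = None
    filtered: GenotypeMatrix | None = None
    env: EnvTable | None = None
    current: ClimateGrid | None = None
    future: ClimateGrid | None = None
    adaptive: OutlierSet | None = None
    lfmm = None
    truth = None


def run_pipeline(cfg: RunConfig, resume: bool = True) -> dict:
    """Execute all stages in dependency order; returns a run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg) | {"config_hash": cfg.resolved_hash()}, indent=1, default=str)
    )
    state = PipelineState()
    report: dict[str, object] = {"config_hash": cfg.resolved_hash(), "stages": []}
    upstream_ran = False
    for stage in STAGES:
        fn = globals()[f"_stage_{stage}"]
        if resume and not upstream_ran and _stage_done(cfg, outdir, stage):
            log.info("stage %s: up to date, loading artifacts", stage)
            fn(cfg, outdir, state, load_only=True)
            report["stages"].append({"stage": stage, "status": "cached"})
            continue
        upstream_ran = True
        log.info("stage %s: running", stage)
        try:
            artifacts = fn(cfg, outdir, state, load_only=False)
        except Exception as exc:
            report["stages"].append({"stage": stage, "status": "failed", "error": str(exc)})
            (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
            raise RuntimeError(f"pipeline stage {stage!r} failed (see {outdir/'report.json'})") from exc
        _mark_done(cfg, outdir, stage, artifacts)
        report["stages"].append({"stage": stage, "status": "ok", "artifacts": artifacts})
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


# -------------------------------------------------------------- stages


def _stage_simulate(cfg: RunConfig, outdir: Path, state: PipelineState, load_only: bool):
    from .synthdata import SimulationConfig, population_env_table, simulate_scenario, write_scenario, GroundTruth

    sim_dir = outdir / "scenario"
    if cfg.simulate:
        sim_cfg = SimulationConfig(**({"seed": cfg.seed} | cfg.sim_overrides))
        g, truth, cur, fut = simulate_scenario(sim_cfg)
        state.genotypes, state.truth, state.current, state.future = g, truth, cur, fut
        state.env = population_env_table(g, cur, truth)
        if not load_only:
            write_scenario(sim_dir, g, truth, cur, fut)
        return [str(sim_dir)]
    # real inputs
    state.genotypes = read_vcf(cfg.vcf, cfg.samples)
    if cfg.env_csv:
        state.env = EnvTable.from_csv(cfg.env_csv)
    if cfg.current_grids:
        state.current = read_grid_stack(cfg.current_grids, "current")
    if cfg.future_grids:
        state.future = read_grid_stack(cfg.future_grids, "future")
    return []


def _stage_filter(cfg: RunConfig, outdir: Path, state: PipelineState, load_only: bool):
    g, rep = filter_snps(state.genotypes, cfg.max_missing, cfg.min_maf)
    state.filtered = g
    if load_only:
        return []
    write_vcf(g, outdir / "filtered.vcf")
    write_samples_csv(g, outdir / "samples.csv")
    (outdir / "filter_report.json").write_text(json.dumps(dataclasses.asdict(rep), indent=1))
    return ["filtered.vcf", "samples.csv", "filter_report.json"]


def _stage_structure(cfg: RunConfig, outdir: Path, state: PipelineState, load_only: bool):
    g = state.filtered
    fst = weir_cockerham_fst(g)
    pca = genotype_pca(g, n_components=10)
    nei = nei_distance(g.population_frequencies())
    nwk = neighbor_joining(nei)
    counts, sizes = sfs_input_from_genotypes(g)
    proj = max(2, int(np.min(sizes)))
    sfs = project_sfs(counts, sizes, proj)
    state._pca_scores = pca.scores  # demographic proxies for the models stage
    state._fst = fst
    if load_only:
        return []
    fst.per_locus.to_csv(outdir / "fst_per_locus.csv", header=["fst"])
    fst.pairwise.to_csv(outdir / "fst_pairwise.csv")
    fst.population_specific.to_csv(outdir / "fst_population_specific.csv", header=["beta_wt"])
    pd.DataFrame(
        {"multilocus_ratio_of_sums": [fst.multilocus], "mean_of_ratios": [fst.mean_of_ratios]}
    ).to_csv(outdir / "fst_summary.csv", index=False)
    pd.DataFrame(pca.scores, index=g.individual_ids).to_csv(outdir / "pca_scores.csv")
    (outdir / "nj_tree.nwk").write_text(nwk + "\n")
    pd.DataFrame({"minor_count": range(len(sfs.folded)), "mass": sfs.folded}).to_csv(
        outdir / "sfs_folded.csv", index=False
    )
    return ["fst_per_locus.csv", "fst_pairwise.csv", "fst_population_specific.csv",
            "fst_summary.csv", "pca_scores.csv", "nj_tree.nwk", "sfs_folded.csv"]


def _env_for_individuals(state: PipelineState) -> EnvTable:
    env = state.env
    g = state.filtered
    if env.n_sites == g.n_individuals:
        return env
    rows = env.data.loc[g.populations].to_numpy()
    return EnvTable(pd.DataFrame(rows, index=g.individual_ids, columns=env.variables),
                    dict(env.categories), env.scaled)


def _stage_scan(cfg: RunConfig, outdir: Path, state: PipelineState, load_only: bool):
    g = state.filtered
    env_ind = _env_for_individuals(state)
    assoc = fit_lfmm(g, env_ind, k=cfg.k_lfmm, n_runs=cfg.lfmm_runs, seed=cfg.seed)
    pc = pcadapt_scan(g, k=cfg.k_pcadapt, seed=cfg.seed)
    fst_sets = [pc.significant(cfg.fdr_q)]
    for path in cfg.external_outliers:
        fst_sets.append(OutlierSet.read(path))
    adaptive = intersect_outliers(assoc, fst_sets, cfg.fdr_q)
    state.adaptive = adaptive
    state.lfmm = assoc
    if load_only:
        return []
    long = assoc.q.stack().rename("q").to_frame()
    long["p"] = assoc.p.stack()
    long["z"] = assoc.z.stack()
    long.index.names = ["locus", "variable"]
    long.reset_index().to_csv(outdir / "lfmm_associations.csv", index=False)
    pc.q.to_csv(outdir / "pcadapt_q.csv")
    adaptive.write(outdir / "adaptive_loci.txt")
    _write_bed(g, adaptive.ids, outdir / "adaptive_loci.bed")
    return ["lfmm_associations.csv", "pcadapt_q.csv", "adaptive_loci.txt", "adaptive_loci.bed"]


def vcf_to_bed_interval(chrom: str, pos_1based: int) -> tuple[str, int, int]:
    """The single 1-based VCF position to 0-based half-open BED conversion."""
    return chrom, pos_1based - 1, pos_1based


def _write_bed(g: GenotypeMatrix, ids: list[str], path: Path) -> None:
    by_id = {l.id: l for l in g.loci}
    with open(path, "w") as fh:
        for lid in ids:
            l = by_id[lid]
            chrom, start, end = vcf_to_bed_interval(l.chrom, l.pos)
            fh.write(f"{chrom}\t{start}\t{end}\t{lid}\n")


def _stage_models(cfg: RunConfig, outdir: Path, state: PipelineState, load_only: bool):
    g = state.filtered
    fst = state._fst
    coords = g.population_coords()
    env_pop = state.env if state.env.n_sites == len(coords) else None
    if env_pop is None:
        raise RuntimeError("models stage needs a population-level environment table")
    pruned, drop_log = prune_collinear(env_pop)
    dists = build_distances(coords, pruned, cfg.resistance or None)
    gen = fst.pairwise_linearized()

    rows = []
    geo = dists["geo"]
    for name, dm in dists.items():
        m = mantel(gen, dm, cfg.mantel_permutations, cfg.seed)
        rows.append({"model": name, "test": "mantel", "r": m.r, "p": m.p_value})
        if name != "geo":
            pm = partial_mantel(gen, dm, geo, cfg.mantel_permutations, cfg.seed)
            rows.append({"model": name, "test": "partial_mantel|geo", "r": pm.r, "p": pm.p_value})
    mantel_table = pd.DataFrame(rows)
    support = rcm(gen, dists, n_perm=1, seed=cfg.seed)
    ranking = mlpe_fit(gen, dists)

    pc = pcnm(geo)
    spatial = pc.half_positive().to_numpy()
    demo = state._pca_scores[:, :2]
    # population-level demographic proxies: average individual PC scores
    demo_pop = pd.DataFrame(demo, index=g.populations).groupby(level=0, sort=False).mean().to_numpy()
    response = _pcoa_response(gen)
    part = rda_partition(response, spatial, demo_pop, pruned.zscored().values(),
                         n_perm=cfg.rda_permutations, seed=cfg.seed)
    state._models = {"ranking": ranking, "support": support, "partition": part}
    if load_only:
        return []
    for name, dm in dists.items():
        dm.to_csv(outdir / f"dist_{name}.csv")
    mantel_table.to_csv(outdir / "mantel_tests.csv", index=False)
    support.to_csv(outdir / "rcm_support.csv")
    ranking.to_csv(outdir / "mlpe_ranking.csv")
    pc.vectors.to_csv(outdir / "pcnm_vectors.csv")
    part.fractions.to_csv(outdir / "variance_partition.csv", header=["fraction"])
    with open(outdir / "variance_partition.txt", "w") as fh:
        fh.write("Three-set variance partition (adjusted R2 fractions)\n")
        fh.write(f"full-model permutation p = {part.p_full:.4f}\n")
        for k, v in part.fractions.items():
            fh.write(f"  {k:9s} {v: .4f}\n")
        for k, v in part.p_pure.items():
            fh.write(f"  p(pure {k}) = {v:.4f}\n")
        fh.write(f"fully supported RCM models: {fully_supported(support)}\n")
        if drop_log:
            fh.write("pruned variables:\n")
            for var, why in drop_log:
                fh.write(f"  {var}: {why}\n")
    return ["mantel_tests.csv", "rcm_support.csv", "mlpe_ranking.csv", "pcnm_vectors.csv",
            "variance_partition.csv", "variance_partition.txt"]


def _pcoa_response(gen: DistanceMatrix) -> np.ndarray:
    """Principal-coordinate embedding of a genetic distance matrix, used
    as the multivariate response for redundancy analysis."""
    n = gen.n
    j = np.eye(n) - np.ones((n, n)) / n
    gmat = -0.5 * j @ (gen.values**2) @ j
    vals, vecs = np.linalg.eigh(gmat)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals[0], 1e-30) * 1e-9
    return vecs[:, pos] * np.sqrt(vals[pos])


def _stage_offset(cfg: RunConfig, outdir: Path, state: PipelineState, load_only: bool):
    if state.current is None or state.future is None:
        log.info("no climate grids available: offset stage skipped")
        return []
    g = state.filtered
    env_pop = state.env
    assoc = state.lfmm
    adaptive_ids = state.adaptive.ids if state.adaptive else []
    if len(adaptive_ids) < 2:
        # fall back to the GEA hits alone so the stage remains runnable
        adaptive_ids = assoc.significant(cfg.fdr_q).ids
    if len(adaptive_ids) < 2:
        log.info("fewer than 2 adaptive loci: offset stage skipped")
        return []

    sig_by_var = {
        v: [lid for lid in assoc.q.index[assoc.q[v] < cfg.fdr_q] if lid in set(adaptive_ids)]
        for v in assoc.q.columns
    }
    future_pop = _future_env_at_pops(state)
    rres = rona(g, env_pop, future_pop, sig_by_var)

    keep = [i for i, lid in enumerate(g.locus_ids) if lid in set(adaptive_ids)]
    g_adapt = g.subset_loci(np.array(keep))
    env_ind = _env_for_individuals(state)
    model = gf_fit(g_adapt, env_ind, n_trees=cfg.gf_trees, seed=cfg.seed)
    gf_grid = gf_offset(model, state.current, state.future)

    gen = frequency_distance(g, adaptive_ids)
    gdm_model = gdm_fit(gen, env_pop.subset(list(state.current.variables)), g.population_coords())
    surface = gdm_offsets(gdm_model, state.current, state.future)
    state._offset = {"rona": rres, "gf": gf_grid, "gdm": surface}
    if load_only:
        return []
    rres.rona.to_csv(outdir / "rona.csv")
    rres.per_locus.to_csv(outdir / "rona_per_locus.csv")
    from .grids import write_esri_ascii

    write_esri_ascii(outdir / "gf_offset.asc", np.where(np.isnan(gf_grid), -9999, gf_grid),
                     state.current.lat0, state.current.lon0, state.current.cell_size, state.current.mask)
    surface.write(outdir, prefix="gdm_offset_")
    return ["rona.csv", "rona_per_locus.csv", "gf_offset.asc", "gdm_offset_table.csv"]


def _future_env_at_pops(state: PipelineState) -> EnvTable:
    """Future environment sampled at the population cells."""
    g = state.filtered
    cur, fut = state.current, state.future
    coords = g.population_coords()
    rows = np.clip(np.round((cur.lat0 - coords["lat"].to_numpy()) / cur.cell_size).astype(int), 0, cur.shape[0] - 1)
    cols = np.clip(np.round((coords["lon"].to_numpy() - cur.lon0) / cur.cell_size).astype(int), 0, cur.shape[1] - 1)
    flat = rows * cur.shape[1] + cols
    vals = fut.env_at_cells(flat)
    df = pd.DataFrame(vals, index=coords.index, columns=fut.variables)
    return EnvTable(df, {v: "climate" for v in fut.variables}, scaled=True)
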