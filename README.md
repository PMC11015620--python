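# landgen

Landscape-genomics inference for reduced-representation SNP studies:
population structure, genotype–environment association (GEA),
isolation-by-distance/environment/resistance model competition, and
genomic offset under climate-change scenarios.

The package targets the common design in plant and animal landscape
genomics: a few dozen populations of a handful of individuals each,
genotyped at a few thousand biallelic SNPs, with per-site environmental
variables and current/future climate rasters. It implements the full
chain from VCF to offset maps, and ships a synthetic-data generator
with recorded ground truth so every stage can be validated by
parameter recovery rather than by eyeballing.

## What it computes

- **Structure** (`landgen.popgen`): Weir–Cockerham (1984) θ with
  per-locus variance components, multilocus ratio-of-sums and pairwise
  estimates, Weir–Goudet population-specific β, genotype PCA with
  per-locus mean imputation, Nei (1972) distance, neighbor joining,
  PERMANOVA, and hypergeometric projection of the folded site
  frequency spectrum.
- **GEA scans** (`landgen.gea`): a ridge latent-factor mixed model
  (LFMM) testing each locus against each environmental variable with
  K latent factors absorbing structure, z-scores combined over
  bootstrap runs and recalibrated by the genomic inflation factor
  λ = median(z²)/χ²₀.₅(1); a PCA-outlier scan (robust Mahalanobis
  distance of per-locus loadings on the top-K PCs); Benjamini–Hochberg
  FDR control; and the intersection rule that keeps GEA hits also
  present in a differentiation-outlier set.
- **Model competition** (`landgen.landscape`): Mantel and partial
  Mantel tests on F_ST/(1−F_ST) or frequency distances vs. geographic,
  environmental and resistance matrices; reciprocal causal modeling
  (differences of reciprocal partial Mantel r); maximum-likelihood
  population-effects (MLPE) regressions ranked by AIC with the
  ΔAIC > 2 rule; PCNM spatial eigenvectors; three-set partial-RDA
  variance partitioning with permutation tests; Schoener's D /
  Warren's I niche overlap with a permutation equivalency test; and
  TSS-based suitability thresholding.
- **Genomic offset** (`landgen.offset`): RONA (per-locus linear
  regressions of population allele frequency on climate, projected to
  the future and averaged with R² weights), gradient-forest turnover
  functions and offsets (per-locus random forests, split importance
  pooled into monotone climate transforms), and GDM local/forward/
  reverse offsets (monotone I-spline dissimilarity model) including
  migration distance and initial bearing to the minimum-offset cell.
- **Synthetic scenarios** (`landgen.synthdata`): Gaussian-random-field
  climate layers, Balding–Nichols drift calibrated to a target F_ST,
  logistic allele-frequency clines for adaptive loci, missing data,
  and future = current + per-variable shifts, with a ground-truth
  sidecar (adaptive locus ids, slopes, true per-cell |Δp|).

## Worked example

```python
from landgen.synthdata import SimulationConfig, simulate_scenario, \
    individual_env_table
from landgen.popgen import weir_cockerham_fst
from landgen.gea import fit_lfmm

cfg = SimulationConfig(n_pops=24, n_ind_per_pop=8, n_neutral=1000,
                       n_adaptive=50, beta=1.5, fst_target=0.10, seed=11)
g, truth, current, future = simulate_scenario(cfg)

fst = weir_cockerham_fst(g)
print(f"multilocus F_ST = {fst.multilocus:.3f}")

env = individual_env_table(g, current, truth)
assoc = fit_lfmm(g, env, k=2, n_runs=10, seed=11)
q = assoc.q["env1"]
hits = set(q.index[q < 0.10])
adaptive = set(truth.adaptive_locus_ids)
print(f"power = {len(hits & adaptive) / 50:.2f}, "
      f"empirical FDR = {len(hits - adaptive) / max(len(hits), 1):.3f}")
```

Output:

```
multilocus F_ST = 0.111
power = 0.94, empirical FDR = 0.130
```

The drift parameter is recovered (target 0.10, estimate within the
expected sampling spread), and the scan finds 47 of the 50 planted
clinal loci at q < 0.10 while keeping the realized false-discovery
rate near the nominal 10%.

The same chain runs from the shell:

```bash
landgen run-all --outdir my_run --seed 11
```

which writes filtered genotypes, F_ST tables, association tables,
outlier lists, distance matrices, model rankings, the variance
partition, and RONA/GF/GDM offset surfaces, each stage with a
provenance sidecar enabling stage-level resume.

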