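# Methods

This note documents the models behind `landgen`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Synthetic scenarios and ground truth

The generator (`landgen.synthdata`) emulates a mid-sized landscape
genomics design: 26 populations of 8 diploid individuals on a
40×40-cell landscape, 1,000 neutral plus 50 adaptive biallelic SNPs,
multilocus F_ST ≈ 0.10, 11% missing genotypes, and five environmental
layers of which the first drives adaptation. These defaults are the
study conditions for all recovery tests; unit tests shrink the grid
and locus counts for speed, never the structure.

**Climate layers** are Gaussian random fields, synthesized by
kernel convolution: white noise smoothed with a Gaussian kernel of
standard deviation `autocorr_range` cells under wrap-around boundary
conditions, then standardized to mean 0 / sd 1 over unmasked cells.
Wrap-around leaves mild periodic artifacts at the grid edge, which at
these grid sizes are irrelevant to the statistics computed. The
future scenario adds a per-variable constant (`future_delta`, default
+1 sd on the driving variable), matching the practice of averaging a
few downscaled projections into a single shifted layer.

**Genotypes** follow the Balding–Nichols model: ancestral frequency
p₀ ~ U(0.05, 0.95) per locus, population frequency ~ Beta with mean p₀
and shape (1−F)/F for F = `fst_target`; the expected Weir–Cockerham
F_ST equals F, which the calibration tests confirm within ±0.03.
Adaptive loci shift the drawn frequency on the logit scale by
β·z (β default 1.5, z the standardized driving variable at the
population's cell), giving logistic allele-frequency clines.
Frequencies are clipped to [0.001, 0.999] before binomial sampling;
realized monomorphic loci are retained and handled downstream.
Missingness is completely at random (the field missingness mechanism
is unknown), at rate 0.11 by default.

**Ground truth** records the adaptive locus ids, each locus's β and
driving variable, and a per-cell *true offset*: the mean over adaptive
loci of |p(z + δ) − p(z)| evaluated on the deterministic cline (drift
noise excluded). Offset engines are scored against this surface.

What the generator does **not** emulate: linkage disequilibrium,
shared demographic history between populations (populations are
exchangeable draws), selection dynamics through time, and spatially
structured missingness. Passing recovery tests therefore demonstrate
correctness of the estimators under drift + clines, not robustness to
demographic confounding along the gradient — the hard case for GEA in
real data.

## Structure statistics

Weir–Cockerham variance components a, b, c are computed per locus from
per-population sample sizes, allele frequencies and heterozygote
frequencies; loci with fewer than two populations of data (or average
sample size ≤ 1) are skipped and counted. The multilocus estimate is
the ratio of sums Σa/Σ(a+b+c) (the per-locus average is also emitted);
pairwise entries recompute the components from the two populations
alone. Population-specific values use the Weir–Goudet allele-matching
β, ratio-of-sums over loci. Missing genotypes are excluded per locus
per population everywhere except PCA, where they are mean-imputed
(the standard choice for genotype PCA).

Neighbor joining breaks Q-matrix ties to the lexicographically lowest
taxon-index pair and clamps negative branch lengths to zero, moving
the deficit to the sibling branch. PERMANOVA partitions the squared
distances directly (Gower identity), permuting group labels. SFS
projection distributes each locus over hypergeometric weights at the
target size; the folded spectrum is the default because ancestral
states are unknown. Nei distances with no shared alleles are capped
at 30 and flagged rather than returned infinite.

`frequency_distance` — the mean absolute difference of population
allele-frequency vectors — is provided alongside pairwise F_ST as a
genetic dissimilarity. It is the default GDM response (see below).

## GEA scans

The LFMM is solved by a ridge closed form rather than MCMC: for each
environmental variable x, the genotype matrix is shrunk along x's
ridge projection (factor √(λ/(λ+σ²)) on the singular values of x,
λ = `ridge_penalty`, default 1e-5) and the top-K left singular vectors
of the shrunken matrix serve as latent factors; each locus is then
regressed on [x, factors] and the t statistic taken as z. Runs beyond
the first bootstrap individuals — run-to-run variation is what makes
the multi-run median meaningful — and the combined z is the across-run
median (configurable; the combination rule in the original software is
unspecified). p-values come from z²/λ_GIF ~ χ²(1) with
λ_GIF = median(z²)/χ²₀.₅(1). With `calibrate=False, n_runs=1` the
p-values are exact regression t-tests, so K = 0 reproduces simple
linear regression — the contract the unit tests pin down. K is always
user-chosen; a scree helper exists but is never applied silently.

The PCA-outlier scan regresses each locus on the top-K PC scores,
summarizes the K z-scores by Mahalanobis distance under a minimum
covariance determinant estimate (support fraction 0.75), and uses
χ²(K) after genomic-inflation rescaling. In the 1-D case the statistic
is the squared loading robustly scaled with no centering, preserving
the loading rank order. Under the exchangeable-population drift model
every structure axis carries comparable variance, so outlier recovery
requires K near n_pops − 1; with K = 15 on 16 populations, ~95% of
planted F = 0.5 outliers are detected at q < 0.10.

BH-FDR is the step-up procedure with enforced q monotonicity; the
default threshold is q < 0.10. The adaptive set is the intersection of
GEA hits with the union of differentiation-outlier sets (externally
computed sets are accepted as id lists); intersecting can only remove
false positives relative to the union, which the recovery harness
verifies empirically.

## Model competition

Distance predictors: great-circle geographic distance (haversine,
R = 6371 km), Euclidean environmental distances on z-scored variables
per category (climate/soil/topography), and externally computed
resistance matrices loaded from CSV. Collinearity pruning drops the
highest-VIF variable iteratively until all VIF ≤ 10, then one member
of each pair with |r| > 0.8 (the higher mean-|r| member).

Mantel tests correlate upper triangles, permuting one matrix's labels;
`n_perm="exact"` enumerates all n! relabelings. Partial Mantel
correlates the residuals of both matrices on the control and permutes
the response's residual matrix (Legendre's residual-permutation
scheme; the literature is split and this choice is configurable in
principle by permuting labels instead). A response fully explained by
the control returns r = 0 by convention instead of correlating
rounding noise. All permutation p-values use (1 + count)/(1 + n_perm).

RCM support is r_partial(g ~ f | a) − r_partial(g ~ a | f) for every
ordered model pair; "full support" = every off-diagonal row entry
positive (the qualitative rule in the source literature made
operational). MLPE uses Clarke's population-effects covariance — unit
diagonal, ρ/2 between pairs sharing one population, built from the
pair-population incidence so it is positive definite for ρ < 1 — with
ρ profiled over [0, 0.99] by maximum likelihood and k = 4 parameters
in the AIC. ML (not REML) because models with different fixed effects
are compared. PCNM truncates the geographic distance matrix at the
largest minimum-spanning-tree edge (default), replaces exceedances
with 4× the truncation, double-centers and keeps positive-eigenvalue
axes; "half of the positive axes" uses floor for odd counts. The RDA
partition computes Ezekiel-adjusted R² for the 7 subset models and
solves the inclusion–exclusion system exactly; pure fractions are
tested by permuting conditional-model residuals, the full model by
permuting response rows.

## Genomic offset

**RONA.** For each significant locus and variable, population allele
frequency is regressed on the current variable; the per-locus offset
at a population is |slope|·|Δenv| and the population value is the
R²-weighted mean over loci. Regressions run on population frequencies
(not individual dosages) because the cline model is defined at the
population level. Variables rank by significant-locus count, top three
flagged. On default scenarios the estimator tracks the true mean |Δp|
with a mild upward bias (~+10%): R² weighting favors the steepest
clines. The exact internals of the original script are unpublished;
the implementation follows the published description.

**Gradient forest.** Each adaptive locus gets a random-forest
regression (default 500 trees, depth cap ⌈log₂(0.368·n/2)⌉ with n the
number of individuals, the conditioning heuristic quoted in the GF
literature; the correlation threshold r = 0.5 is recorded in the model
config). Split impurity reductions are pooled along each variable's
range, weighted per locus by out-of-bag R² (loci with R² ≤ 0 dropped),
yielding monotone cumulative-importance turnover functions; a locus's
total contribution equals its R². Offset = Euclidean distance between
the turnover-transformed current and future environment of a cell; an
RGB map takes the first three PCs of the transformed vectors.

**GDM.** Pairwise genetic dissimilarity d ∈ [0,1) is regressed on
monotone I-splines (default 3 per predictor, quadratic, knots at the
0/50/100th percentiles; built as reversed cumulative sums of a
B-spline basis) of site environmental values, plus optionally
great-circle distance, through d = 1 − exp(−η) with nonnegative
coefficients. Fitting is IRLS with an NNLS inner solve on the
complementary-log working response; convergence at Δdeviance < 1e-8
(sum-of-squares deviance), error after 100 iterations with the trace
attached. The response used throughout the package is
`frequency_distance` of the adaptive loci: pairwise F_ST between a few
dozen drifting populations saturates and cannot localize where along
the gradient turnover happens, which made offset surfaces unstable in
recovery runs, while the frequency distance recovers the true offset
surface reliably (rank correlation ≥ 0.6 in every tested seed).
Dissimilarities at or above 1 are rescaled below 1 and the factor
recorded.

**Offsets** between two environments drop the fitted intercept and the
geographic term: offset = 1 − exp(−Σ|ΔI-spline features|). The
intercept is baseline dissimilarity at zero environmental separation
(drift, sampling noise) and would make "no change" read as nonzero
offset; the geographic term would penalize distance, contradicting the
no-dispersal-limitation assumption of forward/reverse offsets.
local(i) compares cell i's current and future climate; forward(i) is
the minimum offset from i's current climate to any candidate cell's
future climate (candidates default to future-suitable cells,
toggleable); reverse(i) the minimum from i's future climate to any
current-suitable cell. Ties break by smallest great-circle distance,
then lowest cell index, making surfaces deterministic. Migration
distance is the haversine distance to the forward argmin and bearing
the initial great-circle bearing (0° = north, clockwise); both are 0
when a cell is its own best target.

## Numerical conventions and problem sizes

Missing genotypes use sentinel −1; VCF positions are 1-based, BED
intervals 0-based half-open, converted in one place. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
fixed seed ⇒ bit-identical outputs. Permutation tests use
(1 + count)/(1 + n_perm) except exact enumeration (count/n!).

The recovery and calibration harnesses use scaled problem sizes chosen
to keep the full suite in the low minutes on one CPU while leaving
effect sizes detectable: F_ST calibration at 24 populations × 8
individuals × 1,000 loci over 20 seeds; GEA recovery on the default
adaptive scenario over 3 seeds; model competition at 15 populations
over 20 seeds; type-I calibration with 200 null replicates (Mantel
n = 15 with 199 permutations, PERMANOVA n = 16 with 99, LFMM 40 × 120
with K = 2). Offset oracles run on 3×3 grids where exhaustive
double-loop enumeration is exact.

## Known limitations

- The ridge LFMM is a closed-form approximation; it does not estimate
  K and its calibration under strong gradient-confounded structure is
  untested here (the generator has no such confounding).
- GF turnover uses raw split-importance binning; the band-width
  correlation refinement of the reference implementation is recorded
  in configuration but approximated by the pooled-binning scheme.
- MLPE assumes a single grouping level (populations); hierarchical
  designs are out of scope.
- The equivalency test permutes occurrence points only; the companion
  background test is not implemented.
- Resistance surfaces and suitability masks are inputs; the package
  neither computes circuit-theory resistance nor fits niche-model
  ensembles (it only provides the TSS thresholding statistic).
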