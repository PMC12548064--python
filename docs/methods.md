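# Methods

## Scope and data model

The pipeline tests, per candidate CpG, whether conception by assisted
reproductive technology (ART) is associated with DNA methylation in a
two-timepoint child cohort, and whether that association changes
between birth and a later age. Methylation enters all models as
M-values, `M = log2(β/(1−β))`; β-scale inputs are transformed on read.
The candidate set is the 25-probe *BRCA1*/*NBR2* bidirectional-promoter
manifest bundled with the package (hg19, Illumina EPIC v2.0
annotations).

Raw-array processing (detection-p QC, background correction,
normalization) and reference-based cell-type deconvolution are outside
the package's scope: they require raw intensity data and reference
panels. Precomputed cell-type fractions can instead be supplied on the
sample sheet and included as sensitivity covariates
(`include_cell_fractions=True`), with one reference fraction dropped.

## Cross-sectional association

Within each timepoint dataset, each probe is first filtered by the
robust outlier rule: exclude samples with
`|M − median| > k · MAD`, default `k = 5`, where the MAD is the plain
median of absolute deviations from the median. The MAD is deliberately
**unscaled** (no 1.4826 normal-consistency constant); a
`scale_constant` argument provides the scaled variant. Filtering is a
single pass per probe; a zero MAD (degenerate spread) excludes nothing
and logs a warning. Idempotence holds with respect to the first-pass
median/MAD.

The per-probe model is a linear mixed model with a random intercept
for the 96-well processing plate, fitted by REML:

    M = Xβ + u_plate + ε,   u_plate ~ N(0, τ²),  ε ~ N(0, σ²)

Fixed effects: ART (natural = reference), maternal age (years,
continuous), smoking (two indicators, reference "No"), pre-pregnancy
BMI (three indicators, reference "Normal"; missing BMI → complete-case
exclusion), parity (continuous integer), child's sex (reference
female), multiple pregnancy, and — postnatal models only — child's age
in years. Inference on the ART coefficient is a two-sided Wald test
against the **normal** reference (group sizes are in the hundreds, so a
t reference would be indistinguishable); the 95% CI is ±1.96·SE.
Benjamini–Hochberg adjustment is applied within each timepoint's
25-probe family. `bh_adjust` delegates to statsmodels'
step-up implementation and is property-tested against an explicit
min-over-ranks oracle.

Numerical choices: variance components are profiled by statsmodels'
MixedLM. Its default optimizer occasionally declares non-convergence
(or converges to a degenerate point with infinite log-likelihood) when
τ² is near its boundary, so fits are retried with a fixed optimizer
sequence (L-BFGS, CG, Powell) and accepted only when flagged converged
with finite parameters. A boundary estimate is reported as
`plate_variance = 0`, not an error. If no optimizer converges, the fit
falls back to OLS with `plate_variance = 0` and `converged` still true
(this is the documented singular-variance path); only a fit that fails
outright yields `converged = False` with no p-value.

## Within-child change

Each timepoint's probe values (post outlier filter) are residualized on
sex (+ child's age postnatally) with the same plate random-intercept
structure; residuals are conditional (fixed effects and predicted plate
effects removed), then standardized within the dataset using the n−1
sample SD. A residual SD that is zero relative to the outcome scale
(≤ 1e-10·(max|M|+1)) is a degenerate probe and raises an error.

The per-child outcome is `d = z_postnatal − z_birth` (direction is a
flag; this default means a positive ART coefficient is ART-associated
methylation increasing with age). Only children present — and not
filtered as outliers — at both timepoints contribute. `d` is regressed
by OLS on ART plus the maternal covariates (age, smoking, BMI, parity),
with Wald z inference and BH across the probe family. Fewer than 10
complete pairs aborts the model as unidentifiable in practice. Because
standardization removes location and scale, the analysis is invariant
to affine rescaling of either timepoint's M-values (verified in tests
to optimizer precision).

## Monte-Carlo power

The power model for a single CpG is
`M_i = intercept + delta·X_i + sigma·T_i`, `T_i ~ t(df)`, with defaults
intercept 1.2, delta 0.13, sigma 0.49, df 10. `sigma` multiplies a
standard t draw, so the total noise SD is
`sigma·sqrt(df/(df−2)) ≈ 0.548` at the defaults — this interpretation
analytically reproduces ~80% power at 1,112/365 and is the one adopted.
Each iteration tests the group coefficient of an OLS fit by a two-sided
Wald test at `alpha` (default the Bonferroni threshold
0.05/25 = 0.002); for a single binary covariate the OLS Wald statistic
equals the pooled-variance two-sample z, which is how it is computed
(vectorized over iterations, chunked to bound memory). An analytic
normal-approximation power formula serves as an independent oracle in
tests.

The multiplier search finds the smallest k on a 0.1 grid with
`ceil(k·n)` per group reaching the target power, by exponential
bracketing plus bisection. Every evaluation reseeds the generator with
the spec seed (common random numbers), which keeps the power curve
monotone in k up to discretization and makes the bisection stable.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes:

- **Sizes**: 250 naturally conceived and 105 independent ART children
  by default, plus 14 ART twin pairs each contributing a second child
  (a 119-child ART sheet). Twin deduplication — keeping one random
  child per pair — is a separate downstream operation, mirroring how
  such cohorts are actually cleaned.
- **Timepoint availability**: a child has both samples with probability
  0.972 (natural) / 0.762 (ART); single-timepoint children are birth-only
  with probability 4/7 (natural) / 1/25 (ART).
- **Covariates**: per-group categorical marginals for sex, smoking,
  BMI (including 5.6%/2.9% missingness), parity; maternal age from a
  normal truncated to [17, 45] with means 31.3/33.8 and SD 4.5 (the SD
  is not identified by published group means; 4.5 years is typical of
  pregnancy cohorts and is exposed on CohortSpec). Twins share all
  maternal covariates. Non-paired children are from multiple births
  with probability 2/250 (natural) / 10/91 (ART), so the deduplicated
  ART group contains ~24 multiple-birth children.
- **Postnatal age**: five bands spanning 3–22 years with per-group
  weights matching the observed band counts, uniform within band.
- **Plates**: samples are randomized to ⌈n/96⌉ plates; plate random
  intercepts are Normal(0, plate_sd) with default plate_sd = 0.05
  M-units — a small technical batch effect (~1% of total variance),
  chosen once as a realistic magnitude since within-plate correlation
  is not identified by published summaries.
- **Methylation**: `M = intercept + δ_timepoint·1[ART] + plate + σ·t(ν)`
  with the power model's defaults (1.2, σ = 0.49, ν = 10) and
  configurable per-probe δ at each timepoint.

What it does **not** emulate: child-level random effects (no
within-child correlation beyond shared plate), age trajectories in
methylation, correlation between covariates and methylation (covariate
effects are zero under the generator unless injected), probe-to-probe
spatial correlation, and cell-composition effects. Passing tests
therefore demonstrate statistical correctness of the estimators under
the generator's assumptions — calibrated type-I error, CI coverage,
effect recovery — not robustness to the full complexity of real
cohort data.

## Determinism and problem sizes

All randomness flows through numpy Generators seeded from explicit
integers; cohort and methylation generation derive independent streams
from the spec seed, so repeated runs are bit-identical. The test suite
uses scaled-down simulation sizes chosen to keep the full run around
two minutes: type-I-error checks pool 200 CpG datasets (8 cohorts × 25
probes) per analysis, CI coverage uses 200 replicates at 1,112/365
with an ART-only design, and oracle-equivalence checks use 1,000
random vectors. Monte-Carlo acceptance bands are ±3 binomial SEs of
the nominal value throughout.

## Known limitations

- The Wald/normal reference and REML are fixed choices (flags exist
  for ML and for the scaled MAD); small-sample t-based inference is not
  implemented.
- The change analysis excludes children with an outlier at either
  timepoint (complete-pair analysis); no imputation is attempted.
- `required_multiplier` reports the grid multiplier at which the
  common-random-number power estimate crosses the target; its
  seed-to-seed spread at 10,000 iterations is about ±0.1–0.2.
- The bundled manifest covers only the 25 promoter CpGs; genome-wide
  analysis is out of scope.
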