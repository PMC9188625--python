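# Methods

This note documents the statistical model, the synthetic-cohort generator,
the numerical choices, and the limitations of `sesmap`.

## Estimation model

The core estimator is multi-output (multi-task) ridge regression of the
six z-scored SES indicators on the z-scored design matrix:

    Ŵ = argmin_{W ∈ ℝ^{p×k}}  (1/2n) ‖Y − XW‖_F² + (α/2) ‖W‖_F²

with no intercept (all columns are centered by standardization).  Note the
residual term is normalized by n: `alpha = 0.01` in this convention equals
`n × 0.01` in solvers that penalize the raw residual sum of squares
(`sklearn.linear_model.Ridge`); the test suite verifies this mapping.

Because the Frobenius penalty separates across outcome columns, column j
of the multi-output solution is algebraically identical to the
single-output ridge fit of indicator j alone.  We implement the stated
objective and expose this *separability identity* as a tested invariant
rather than introducing any unstated cross-task coupling penalty: the
joint estimation is a modeling convenience (one coefficient matrix, one
resampling pipeline over all six indicators), not an extra regularizer.

Two solvers return the same minimizer: a closed form via Cholesky solve of
`(XᵀX/n + αI) W = XᵀY/n`, and cyclic coordinate descent with exact
per-coordinate updates, fixed sweep order, full passes, and convergence on
the maximum absolute coefficient change (default tol 1e-8, cap 10,000
sweeps; non-convergence raises with the final max change).  Coordinate
descent is deterministic by construction.

### Design matrix

1. **Indicator orientation** — each indicator is flipped if needed so a
   larger value always means higher SES (the neighborhood indicator is
   deprivation-coded on input and inverted; occupation is coded
   1 = knowledge worker, 0 = manual worker).
2. **Deconfounding** — brain features are residualized on head size and
   BMI (least squares with intercept) before modeling, so downstream
   effects cannot be explained by brain size or adiposity.  The
   residualization is fitted once on the full analysis sample and reused
   inside resampling; refitting per resample is available as an option.
3. **Covariates** — age (centered before powers), sex, age², age·sex,
   age²·sex, fluid IQ, and optionally handedness are appended to the brain
   block and penalized identically (they occupy the same X).  Degenerate
   (constant) covariate columns are dropped with a log entry.
4. **Standardization** — every X and Y column is z-scored with the sample
   (n−1) sd convention.  The convention is recorded with the
   transformation parameters so held-out data can be transformed
   consistently; the package requires complete cases.

## Resampling inference

* **Bagging** (B = 100 by default): n-out-of-n resamples with
  replacement; each draw is re-standardized and refit with the closed
  form; mean/sd and the 5th/95th percentiles summarize each coefficient.
  A resample with a constant column is redrawn and logged.
* **Permutation max-statistic FWE** (R = 1000 by default): outcome rows
  are permuted as a block — all six indicators travel together, so the
  inter-indicator correlation structure survives while the brain-SES
  correspondence is destroyed; X is untouched.  Per permutation, the model
  is refit and the maximum |coefficient| over all p×k cells is recorded.
  Since X is fixed, the normal-equation factorization is computed once and
  reused across permutations; this is exactly equivalent to refitting (a
  test verifies it against from-scratch refits).  P-values use the add-one
  convention `(1 + count)/(1 + R)` with ties counted against significance,
  so p is never 0 and the smallest attainable value at R = 1000 is 1/1001
  ≈ 0.001 — consistent with reporting "all P < 0.001" at that resolution.
* **Observed statistic** — the default compares bagged means against a
  null of plain (single-fit) coefficients.  Nesting full bagging inside
  every permutation is supported (`statistic_mode="bagged_fit"`) but is
  ~B times more expensive and changes results negligibly, since the bagged
  mean closely tracks the plain fit.  Both readings of the procedure are
  therefore one switch apart.

## Laterality statistics

* **Sign counts** — every FWE-significant (feature, indicator) cell on a
  lateralized feature contributes one count to a 2×2 hemisphere-by-sign
  table; a feature significant for two indicators counts twice (a
  deduplicated per-feature mode can be built from the report table).
  Midline features are excluded.  The table is tested with the plain
  Pearson χ² statistic, df = 1 (`n(ad−bc)²` over the margin product); a
  Yates-corrected variant is available but not the default, since plain
  Pearson is the ecosystem default and the choice cannot be pinned from a
  printed statistic alone.  The test refuses tables with a zero margin.
* **Homologue correlation** — Pearson r between the left-member and
  right-member coefficient vectors over homologous pairs, per tissue
  subset (all regions, cortical, subcortical, tracts) and per indicator,
  plus a pooled mode that concatenates the six indicator columns (both the
  pooled-concatenation and per-indicator views are reported side by side,
  as the aggregation is a genuine free choice).  "Bootstrap-uncertainty-
  adjusted" is interpreted as bagged mean divided by bootstrap sd (a
  z-like map); plain bagged means are available via `sd=None`.

## SES structure and annotation

PCA of the indicator block is an eigendecomposition of the 6×6 Pearson
correlation matrix (equivalent to covariance PCA after z-scoring);
explained-variance ratios are eigenvalues/6 and sum to one, and each
component's sign is fixed so its largest-magnitude loading is positive.
Term profiling correlates gray-matter coefficient maps with each column of
a region-by-term matrix (values in [0,1], regions aligned by feature id);
the unique-variance mode residualizes one indicator's map on the other
five (with intercept) before correlating.  No term database is bundled;
any conforming TSV (e.g. a parcellated Neurosynth export) is drop-in, and
the generator builds synthetic fixtures with a planted collinear term.

## Synthetic cohort generator

The generator is the package's testbed; its defaults define the study
conditions used throughout the test suite.

* **Brain features** — `X = Z + head·c_h + bmi·c_b`, with `Z` i.i.d.
  standard normal and confound loadings drawn N(0, 0.3) per feature.  The
  default atlas has 20 cortical, 5 subcortical and 5 tract homologue pairs
  plus 2 midline (brainstem-like) regions: 62 features, a roughly 2:1
  region-to-tract scale-down of the 111-region/48-tract atlases the
  analysis targets.
* **SES indicators** — `y_j = Z·w_j + outcome_noise_sd·(λ_j g + σ_j ε_j)`
  with a single latent factor g, default loadings (.6,.6,.5,.5,.4,.4) and
  unit idiosyncratic noise.  This is the minimal structure consistent with
  moderate positive inter-indicator correlations all below 0.5: the
  closed-form pairwise correlation is λᵢλⱼ/√((λᵢ²+σᵢ²)(λⱼ²+σⱼ²)), at most
  0.265 under the defaults.  The brain signal enters through the
  confound-free part Z, so head size and BMI have no direct path to SES by
  default; `confound_to_ses_sd` adds one for deconfounding stress tests.
* **Planted effects** — half the homologue pairs (and midline features)
  carry effects of magnitude `effect_scale` (default 0.1, the magnitude
  regime of reported standardized brain-SES coefficients).  Of the
  effect-carrying pairs, `asymmetry_fraction` are mirrored: +scale on
  every left cell, −scale on every right cell.  The remaining effect
  coefficients draw signs i.i.d. per (feature, indicator) cell — a
  deliberate choice so that with no planted asymmetry the hemisphere-by-
  sign table has genuinely independent rows and the χ² test is correctly
  calibrated (per-feature shared signs would create correlated count
  blocks and inflate the statistic under the null).
* **Encodings** — degree and income are quantile-binned into 5 bands,
  vehicle count into 4, occupation is a median split, education years and
  neighborhood stay continuous; the neighborhood column is emitted
  deprivation-coded so the orientation step is exercised.  Binning
  attenuates regression slopes (by ≈0.80 for a median split), which is why
  recovery is assessed via correlation with the planted pattern rather
  than absolute coefficient agreement.
* **Confounds** — head size, BMI, IQ ~ N(0,1); age ~ Uniform(40, 70); sex
  ~ Bernoulli(0.5); handedness ~ Bernoulli(0.9).  Identical config and
  seed give bit-identical cohorts.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: left/right homologues are generated
independently (real regional volumes are strongly L/R correlated),
features are mutually independent given confounds (real phenotypes share
global factors beyond head size), indicator marginals and band frequencies
are conventional rather than calibrated to any cohort, and missingness,
site effects and selection biases are absent.  The tests validate the
statistical machinery, not any empirical claim about brains.

## Problem sizes in the validation suite

Parameter-recovery and power analyses run at the generator default
n = 5,000, except the laterality-recovery and power checks which run at
n = 10,000, the population scale this analysis is designed for: with
effect scale 0.1, the standardized planted effect (~0.07) clears the
P < 0.001 max-statistic detection bar comfortably at n = 10,000 (per-cell
detection near 1), whereas at n = 5,000 it sits on the bar and detection
is partial — the familiar regime where family-wise-corrected discovery
requires either larger samples or larger effects.  Null-calibration checks
use n = 1,000, p = 20, R = 200.  Bootstrap-interval coverage is assessed
on continuous indicators with a 1/(1+α) shrinkage-adjusted target, since
ordinal binning attenuates the estimand relative to the planted
coefficient.

## Known limitations

* Inference is resampling-only; no parametric standard errors.
* The pipeline requires complete cases; no imputation.
* Only linear deconfounding; no site/scanner harmonization.
* The benchmark registry ships linear learners plus k-NN; tree ensembles,
  kernel and deep learners are pluggable but not included.
* Ridge shrinkage at α = 0.01 (n-normalized) biases coefficients toward
  zero by a factor ≈ 1/(1+α); interval coverage statements account for it,
  point estimates are reported as fitted.
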