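# Methods

## The index and its invariance

For a sample `s` and an ordered gene pair `(A, B)`, the pair score is the
indicator `1[expr(A, s) > expr(B, s)]`; ties score 0. The prognostic index
is a linear combination of pair scores with coefficients fitted by a
two-stage adaptive-LASSO Cox procedure. The defining property is
*monotone-invariance*: for any strictly increasing per-sample map `f_s`
(quantile normalization, log transforms, affine platform rescalings, any
rank-preserving distortion), the score matrix of `f(X)` equals that of `X`
bit for bit, hence so does every downstream index value. The test suite
asserts this end to end, including with cubic per-sample distortions.

Two consequences shape the implementation:

- **Orientation canonicalization.** For ties-free data the score row of
  `(B, A)` is `1 −` the row of `(A, B)`; the two are perfectly collinear
  and would destabilize any penalized fit. When both genes of an unordered
  pair are prognostic anchors, only one orientation is kept: the one whose
  first gene has the smaller gene-screen p-value, falling back to screen
  order and then lexicographic order. The `GenePairSet` container rejects
  double orientations structurally.
- **No standardization of pair features.** Pair scores share the {0, 1}
  scale. Standardizing would reweight pairs by prevalence, undoing the
  consistency filter's logic, so both penalized stages run on the raw
  binary design. (Standardization as implemented by generic penalized
  solvers is explicitly disabled.)

## Screens and filter

- **Follow-up filter**: samples with observed time strictly below
  `min_followup_months` (default 1 month) are dropped before training;
  the same rule is applied to cohorts scored with a frozen signature.
- **Gene and pair screens**: univariate Cox Wald tests at raw p < 0.05, no
  multiplicity correction — the screens are deliberately liberal
  pre-filters; the cross-validated penalized fit arbitrates the final
  model. Constant and separable features are skipped with a warning rather
  than fitted.
- **Consistency filter**: a pair is abolished when its majority score
  frequency strictly exceeds the threshold (default 0.70); a pair at
  exactly the threshold is retained. Near-constant pairs carry almost no
  ordering information and inflate the design for no benefit. The filter
  compares frequencies (not counts) with a 1e-12 guard so that a 7-of-10
  majority at threshold 0.70 is handled exactly.

## Cox partial-likelihood core

`fit_cox` and the batch univariate screens use the package's own
Newton–Raphson maximizer of the Efron-tied partial likelihood (a fully
vectorized closed form on tie-free data, a tie-group loop otherwise), with:

- step halving to guarantee ascent; convergence at coefficient updates
  below 1e-9;
- **monotone-likelihood detection**: a separable covariate sends the
  likelihood to its supremum only as |β| → ∞. Any Newton trajectory
  exceeding |β| = 20 is declared non-converged with a
  `monotone_likelihood` flag rather than returned as a huge finite
  estimate. A second guard catches separation that flattens the likelihood
  by floating-point underflow before the bound: a "converged" unpenalized
  solution with |β| > 5 and observed information below 1e-6 is reflagged
  as separation;
- Wald two-sided p-values from the inverse observed information.

The implementation is cross-checked in the tests against lifelines (Efron)
on tied and untied data to 1e-5, and against a brute-force partial-
likelihood maximizer on an exhaustive sweep of one-covariate tables with up
to six samples and every event pattern. Kaplan–Meier estimation, the
log-rank test and Harrell's C are delegated to lifelines/scikit-survival;
the time-dependent AUC is the inverse-probability-of-censoring-weighted
cumulative-case/dynamic-control estimator (`cumulative_dynamic_auc`),
chosen as the most common convention for fixed-horizon AUCs of survival
risk scores and exposed as the package's single ROC estimator. Absolute
AUC values can shift by a few points across estimator conventions; only
this one is implemented.

## Adaptive-LASSO Cox

Stage 1 (ridge): L2-penalized Cox fits over a descending grid
(`logspace(3, −2, 21)`), 10-fold cross-validation with event-stratified
folds, penalty selected at the minimum mean Verweij–van Houwelingen
partial-likelihood deviance `−2·[pl_all(β̂_k) − pl_train_k(β̂_k)]`; the
full-data coefficient vector at that penalty defines the weights
`w_j = min(1/|β_ridge_j|, 1e6)`. The cap exists because near-zero ridge
coefficients would otherwise produce numerically infinite penalties.

Stage 2 (weighted LASSO): the weighted penalty `Σ w_j |β_j|` is solved
exactly as a plain LASSO on the rescaled design `x_j / w_j` using a
coordinate-descent Cox elastic-net path solver (tolerance 1e-7), then
mapped back. The penalty grid is data-driven, mirroring glmnet's defaults
(100 path points; smallest penalty 1e-4 of the maximum when samples exceed
features). The penalty at the minimum mean CV deviance is selected
(`lambda_min`); the 1-SE rule is available as an option. An empty model at
every penalty is a valid outcome under the null and is returned with a
warning, not an error.

Fold assignment is keyed to sorted sample ids under the fold seed and
stratified on event status, so the order in which samples arrive can never
change the fitted signature; re-running with identical data, configuration
and seed reproduces the signature byte for byte in its JSON serialization.

## Risk profile and evaluation

Scores are dichotomized at the median (ties to the low group — the
boundary assignment is pinned so results are deterministic; assigning
boundary samples to "low" is conservative for the high-risk claim).
External cohorts are split at their own median by default, with a frozen
training cutoff available. Evaluation reports KM curves and the log-rank
test by group, time-dependent AUC of the continuous index (default
horizons 12/36/60 months; horizons beyond the cohort's follow-up are
dropped with a warning), Harrell's C, and a multivariable Cox fit of the
index with supplied clinical covariates. The "nomogram" deliverable is
that model's linear predictor together with a quantile-binned calibration
table (mean predicted survival vs KM observed, via the Breslow-type
baseline `S0(t)^exp(lp − mean lp)`), not a drawn chart.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes:

- **Expression**: per-gene normal marginals on the log2 scale. Default
  locations N(8, 1.5), scales U(0.8, 1.2) — typical of log-transformed
  tumor expression profiles. The two genes of a planted pair share
  location and scale so the planted indicator is balanced (~50%
  prevalence) and survives the consistency filter.
- **Outcome**: log hazard = Σ β_k · 1[expr(a_k) > expr(b_k)] over planted
  pairs; event times exponential given covariates, so proportional
  hazards holds by construction and a Cox fit of the generator's own truth
  is a valid parameter-recovery oracle (verified: planted β = 1 recovered
  within ±0.15 at n = 2000).
- **Censoring**: independent uniform on (0, U], with U calibrated by
  bisection so the realized censoring fraction meets the target (default
  0.30). The baseline hazard default is 0.04 events/month with a 180-month
  administrative horizon; with substantially lower baselines the uniform
  law cannot censor as little as 30% of protective-arm samples within a
  realistic follow-up window, so these defaults were fixed at generator
  design time.
- **Platform distortion**: optional per-sample affine (`a·x + b`, a > 0)
  or strictly increasing cubic (`a·x³ + b·x + c`, a, b > 0) maps, used to
  exercise the invariance property.
- Time unit is months throughout; a pure-noise `age` covariate is included
  in the clinical table for adjusted-model testing.

What the generator does *not* emulate: negative-binomial count noise,
batch structure beyond monotone distortions, tumor purity, correlated gene
programs, or informative censoring. Passing tests therefore demonstrate
correctness of the algorithms under the model's own assumptions, not
performance on real tumor cohorts, where correlation structure and
non-proportional hazards can only degrade the reported operating
characteristics.

## Problem sizes and operating characteristics

The test suite exercises the full pipeline at 50 genes × 300 samples with
five planted pairs (|β| = 1) and ~30% censoring, 20 replicates — sizes at
which each end-to-end train completes in about a second. Under these
conditions the trained signature recovers at least 4 of 5 planted pairs in
95% of replicates; the only stage at which planted pairs are ever lost is
the p < 0.05 univariate gene screen (the marginal effect of a gene is an
attenuated, sigmoid-averaged version of its pair's log-hazard ratio, and
with several planted pairs the extra hazard variance attenuates it
further). Held-out concordance of the trained index on an independent
cohort of the same design averages 0.722 (range 0.67–0.76 across
replicates), against a ceiling of mean 0.744 (range 0.708–0.771) for the
true-parameter index — the irreducible discrimination available from five
balanced binary indicators with unit log-hazard ratios under 30%
censoring. On null cohorts the pipeline completes with empty or small
signatures, held-out concordance within 0.5 ± 0.07, and uniform null
p-values.

## Numerical and degenerate-input choices

- Ties in expression score 0 ("1 if greater, else 0" — the only reading
  consistent with the definition); relevant for clipped microarray data.
- Constant score vectors cannot be stratified (error), and an empty
  signature scores every sample 0 with a flagged report instead of
  crashing.
- Calibration bins are quantile bins; degenerate (duplicate-edge) bins are
  merged with a log note; constant predictions collapse to a single bin.
- JSON writers sort keys and format floats at 10 significant digits so
  outputs are diffable; the run manifest carries input digests, seeds and
  stage counts.
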