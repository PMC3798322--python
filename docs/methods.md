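# Methods

This note records the models, the defaults and the judgement calls behind
`metamodule`, in the order the pipeline runs.

## Synthetic cohort model

The generator emulates the statistical skeleton of a multi-cohort tumor
expression study; it is first-class, tested code, and every downstream claim
in the test suite is made against its planted ground truth.

Per cohort of n samples:

* **Co-expression module.** A per-sample latent factor f ~ N(0,1) drives the
  module genes: x = λf + √(1−λ²)ε with ε ~ N(0,1), so all module genes
  (including the designated seed gene, member 0) have unit variance and
  pairwise correlation exactly λ².  The default λ² = 0.7 places the module
  comfortably above the r ≥ 0.6 membership threshold while leaving room for
  sampling noise to matter.  All other genes are i.i.d. N(0,1).
* **Survival.** Times are exponential with rate h₀·exp(η),
  η = Σ_g β_g x_g over the planted prognostic genes, where x is the
  unit-variance latent-scale value — so β_g is a log hazard ratio per SD,
  matching how the screen codes expression.  The exponential baseline is the
  simplest choice consistent with proportional hazards; the screen itself is
  semiparametric and never exploits it.  Default h₀ = 0.01 events/month
  gives a median event time near 6 years, a realistic relapse scale.
* **Censoring.** Administrative-uniform C ~ U(0, L).  L is solved with
  Brent's method so that the *expected* censored fraction,
  mean over samples of (1 − e^(−rate·L))/(rate·L), equals the requested
  rate (default 0.30).  This keeps censoring independent of expression
  given the linear predictor and exactly calibrated on average.
* **Platforms.** Even-indexed cohorts are written on a single-channel
  scale (per-cohort scale factor, +8 offset, log2-intensity-like);
  odd-indexed cohorts are mean-centred per gene (dual-channel,
  log-ratio-like).  Scaling a gene's whole row leaves correlations and
  per-SD hazard ratios untouched, which is the point: the pipeline must be
  invariant to platform scale, and the tests exercise that.
* **Clinical covariates.** Age, tumor size, grade, ER and nodal status are
  drawn independently of expression by default.  A `grade_confounding` knob
  correlates the grade latent with the module factor for confounded
  multivariate experiments; it defaults to 0 so that the multivariate
  "effect retained after adjustment" checks are run under the no-confounding
  condition they assert.
* **Endpoints.** All cohorts record relapse-free survival except the last,
  which records overall survival — enough to exercise endpoint bookkeeping
  without complicating the design.

Default design: 6 cohorts of (198, 286, 159, 295, 344, 353) samples
(1635 total), 2000 genes, a 30-gene module, a quarter of the universe
annotated to the screened arm.

What the generator does **not** emulate: copy-number structure, probe-level
noise, batch effects, missingness mechanisms, correlated null genes, or
non-proportional hazards.  Passing tests therefore demonstrate correctness
of the statistical machinery and its operating characteristics under a
clean factor model — not robustness to the full messiness of repository
microarray data.

## Pre-processing conventions

* **"Already logged" heuristic:** a single-channel matrix with max ≤ 30 and
  min ≥ −10 is treated as logged; anything else is transformed with
  log2(x+1) (the +1 keeps zero intensities finite; at intensities in the
  hundreds the offset is negligible).  Dual-channel matrices always pass
  through.
* **Probe collapsing:** probes mapping to no gene, an empty symbol, or more
  than one gene are dropped (logged); multi-probe genes are averaged
  arithmetically; output rows are sorted lexicographically.  Collapsing is
  idempotent.
* **Missing data:** genes with > 20% missing values in a cohort are dropped
  from that cohort only; remaining gaps are handled pairwise-complete in
  correlations and listwise in Cox fits.
* **Symbols** are upper-cased before matching; **no cross-cohort
  normalisation** is ever applied — every statistic is computed
  within-cohort and combined on the estimate scale.

## Survival screen

Expression enters the per-cohort Cox model as a continuous covariate
standardised to unit SD within the cohort, making log-HRs comparable across
platforms for pooling (median splits are used only for Kaplan–Meier display
and the covariate tables).  Ties use the Efron approximation.  The
single-covariate fits are done by an in-package Newton solver on the Efron
partial likelihood with analytic gradient/information, step-halving, and a
|β| ≤ 50 divergence guard; the risk-set/tie structure is precomputed once
per cohort and reused across genes, which makes a 5000-gene × 6-cohort
screen a ~15 s operation on one CPU.  The solver is cross-checked against
lifelines (agreement to ~1e-4, the level of lifelines' own convergence
tolerance) and lifelines remains the fitter for the multivariate covariate
models.  Degenerate inputs — constant expression, fewer than 10 events,
non-convergence — yield results flagged unusable and excluded from pooling
rather than exceptions.

Pooling is DerSimonian–Laird (method-of-moments τ², truncated at 0), with
the combined p taken as the Wald p of the pooled estimate — the natural
companion of inverse-variance pooling; Fisher/Stouffer p-combination is
deliberately not offered.  K = 1 passes through with τ² = 0.  The cascade
requires per-cohort p < 0.005 in ≥ 3 cohorts, combined p < 0.005, and
measurement in ≥ 3 cohorts; genes measured in fewer cohorts are reported
but can never pass.  Ties at the median in `km_stratify` go to the
low-expression arm.

A note on marginal vs conditional effects: when several independent
prognostic genes act simultaneously, each univariate fit omits the others,
and the non-collapsibility of the hazard ratio attenuates every marginal
estimate below its conditional value (with ten β = 0.6 genes the marginal
pooled estimate is ≈ 0.30).  The screen's detection power is barely
affected, but parameter-recovery statements are only meaningful for a
single planted gene, and that is how the estimator-recovery checks are run.

## Co-expression module

Correlations are pooled on the Fisher-z scale (var 1/(n−3)) with the same
DL engine (asserted identical to 1e-12 in the tests).  |r| = 1 is clamped
to 0.999999 before atanh and flagged; the seed is never its own member.
The r ≥ 0.6 threshold applies to the *back-transformed pooled* r, not to
per-cohort values, and membership additionally requires a positive pooled
correlation and two-sided combined p < 0.001 with ≥ 3 contributing cohorts.
The module score is the plain mean of member-gene values per sample
(≥ 50% member coverage required); a z-score-mean variant is available via
a flag for cross-platform pooling of scores.

## Signature scoring

Activation = mean z-scored expression of present up tags − mean of present
down tags (genes z-scored across the scanned samples, population SD;
constant genes contribute 0).  This is the package's single biggest
interpretive choice — tag-based activation scoring has no canonical
formula — and it was chosen for three provable properties the tests pin
down: invariance to per-gene affine rescaling, exact antisymmetry under
swapping the tag lists, and an exactly-2 score for a sample sitting at
+1 SD on every up tag and −1 SD on every down tag.  Alternative scorers
can be passed to `activation_matrix`.  At least 5 up tags must be present.
The activation PCA fixes component signs by forcing the first signature's
loading non-negative.  Overlap tests are exact hypergeometric tails.

## Stratified contrast and reversal query

The >60%/<10% stratification is interpreted as expression percentiles
within the cohort, with strict inequalities (ties at a cut fall into the
discarded middle band).  The two-sample test is Welch's t — the arms are
4:1 unbalanced by construction, so equal variances are not assumed.  No
multiple-testing correction is applied when building the query (the cap on
list length is the operative filter); a BH-FDR flag exists and defaults
off.  Queries are exported as plain GRP lists capped at 500 per side.

The reversal score places each query gene at a normalized rank position in
[−1, 1] within the drug profile (most down-regulated = −1) and reports
mean(up positions) − mean(down positions).  The ±2 extremes are attained
exactly only when each list's genes occupy extreme positions — with a
multi-gene list the block mean is necessarily inside (−1, 1) — so the
extreme-value checks use singleton lists at the profile's two ends, plus a
block check that large lists approach the extremes.

## Numerical conventions

* Random draws flow from `numpy` SeedSequences spawned per cohort, so
  adding cohorts never reshuffles earlier ones and every run is exactly
  reproducible under a fixed seed.
* Fixture TSVs are written at %.17g so read-back is bit-exact.
* SDs use ddof=1 for Cox standardisation (sample convention) and ddof=0
  for signature z-scores (population convention; any consistent choice is
  cancelled by the affine invariance).
* DL τ² is truncated at zero; Q is reported untruncated.

## Problem sizes used in the checks

The acceptance checks run at deliberately modest scale: specificity on
5000 null genes × 6 cohorts of n = 200 (30% censoring); sensitivity with
10 planted β = 0.6 genes in 6 cohorts of n = 300 plus 20 single-plant
replicates for estimator recovery; module recovery with 30 planted genes at
λ² = 0.7 in a 1000-gene universe across 6 cohorts of n = 300; 1000 random
pooling inputs against the independent reference.  These sizes give the
binomial/sampling margins the assertions need while keeping a full run in
tens of seconds.

## Known limitations

* Pooled per-SD hazard ratios will not numerically match analyses that
  fitted raw log2 expression units; the per-SD convention is internal and
  consistent, not a reproduction of any particular published coefficient.
* The Wald-on-pooled combined p is one of several defensible combination
  rules; rankings are insensitive but absolute p-values differ across rules.
* DL confidence intervals are slightly anti-conservative when K is small
  and τ² > 0 (the coverage test asserts the 0.90–0.99 band, not nominal
  0.95); a Knapp–Hartung adjustment is a natural extension.
* No proportionality diagnostics beyond convergence flags; time-varying
  effects, competing risks and cure fractions are out of scope.
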