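# Methods

## The estimation problem

Control arms of large-animal MI experiments report a raw mean percentage
outcome (IS/AAR, IS/LV or EF) per arm. Because percentages are directly
comparable across studies, the effect size is the raw mean itself, with
sampling variance v_i = sd_i²/n_i (squared standard error of a mean). How the
original analyses derived per-study variances for raw means is not generally
reported; sd²/n is the conventional choice and is what the synthetic
generator emits, so the package treats it as an explicit interpretation
rather than a fact about any particular dataset.

The random-effects model y_i = x_iᵀβ + u_i + e_i with u_i ~ N(0, τ²),
e_i ~ N(0, v_i) is fitted by REML. The restricted log-likelihood is profiled
in τ² alone (β is solved in closed form at each candidate τ²) and maximized
by derivative-free bounded Brent search on [0, 10⁴] points² with absolute
tolerance 1e-10; the boundary τ² = 0 is compared explicitly because a bounded
optimizer cannot land exactly on it. The search-interval cap and tolerance
were chosen so the optimizer is verifiable against an exhaustive grid search
of the same likelihood, which the test suite does on small instances.

Inference is z-based throughout (CI = estimate ± 1.959964·se, Wald chi-square
omnibus tests, normal-reference pairwise contrasts), the long-standing
default style of mixed-effects meta-analysis software. No Knapp–Hartung
small-sample adjustment is applied, and no multiplicity correction is applied
to post-hoc contrasts by default (Bonferroni/Holm are available as options).
A p-value below 0.05 (strict) is treated as significant; when a
multivariable omnibus test is non-significant the pipeline does not proceed
to post-hoc contrasts.

## Moderator encoding and reference levels

Categorical moderators (species, strain, sex, occlusion, vessel, approach,
co-medication, immunosuppression, quantification) are dummy-coded against a
reference level; continuous moderators (follow-up in hours, ischemia in
minutes, quality points, weight in kg, age in weeks) enter untransformed in
those canonical units so each coefficient reads as points per unit.
Unreported categories are their own levels, never dropped.

Internally every model is fitted once in a canonical parameterization
(dummies against the alphabetically first observed level) and then mapped to
the requested reference through an exact integer reparameterization matrix
(β' = Lβ, Cov' = L Cov Lᵀ). This makes coefficients, covariances and all
pairwise contrasts exactly invariant — to floating-point roundoff, not just
optimizer tolerance — under any choice of reference level. Refitting per
reference would instead propagate ~1e-7-level differences through the scalar
τ² search.

Rank deficiency is detected by SVD with tolerance 1e-10 × (largest singular
value); aliased columns are identified by pivoted QR and named in the error,
never silently dropped. The joint multivariable model is complete-case;
sparsely reported moderators (ischemia duration, weight, age) are "added
separately": each is refitted as joint model + that single term on its own
complete-case subset. Entering ischemia duration automatically restricts the
fit to temporary-occlusion rows, since the variable does not exist elsewhere.

R² = max(0, 1 − τ²_residual/τ²_null) with τ²_null from the intercept-only
REML fit on the identical row set, capped at 1. Univariable tables report
per-level subgroup means by subgroup random-effects pooling (not regression
fitted values); both readings are defensible and subgroup pooling is the
package default.

A single-study "pool" (k = 1, possible after aggressive subsetting) returns
the study's own values with τ² = 0 and a degenerate flag rather than erroring.

## Mortality

Death fractions are analyzed on the raw proportion scale so coefficients read
as percentage points per unit (no logit/arcsine transform). Two sequential
measurements combine as 1 − p_total = (1 − p₁)(1 − p₂) with effective n of
(n₁ + n₂)/2; the combination is symmetric and associative by construction.

The "1/√n" weighting rule admits two readings and both are implemented:

- `se_inverse_sqrt_n` (default): SE ∝ 1/√n, so regression weight ∝ n.
  Down-weighting large studies is statistically perverse, hence the default.
- `weight_inverse_sqrt_n`: the literal weight = 1/√n.

Weights are normalized to sum to k before use, making every result exactly
invariant to global weight rescaling. In weighted pooling the proxy variances
v_i = ĉ/w_i are calibrated with ĉ the weighted mean squared deviation about
the weighted mean (the classic analytic-weights variance); this leaves the
point estimate untouched and gives the CI a data-driven scale, after which
REML pooling proceeds as usual and the CI is clipped to [0, 100]%. In
weighted meta-regression the normalized inverse weights are used directly as
variances with τ² profiled on top; τ² then absorbs the binomial residual
variation, so the coefficient standard errors remain on the right scale even
though the proxy scale is arbitrary. Records with total < 2 are kept but
flagged in the log.

## Prediction

A scenario assigns one level per categorical moderator and values for the
continuous moderators; its prediction is the linear predictor xᵀβ with
confidence-of-mean interval se = √(xᵀ Cov x). A new-study interval adding
τ²_residual is available by flag but off by default, because prediction grids
conventionally present expected means. Follow-up enters linearly; values
outside the fitted data range are flagged `extrapolated_follow_up` and
rendered in parentheses with a `*` marker. EF scenarios with follow-up below
72 h are flagged `stunning_window` and withheld (rendered `—†`): early
post-reperfusion EF is confounded by myocardial stunning. The 72-hour
threshold is an interpretation, configurable per call, not an established
constant.

The auxiliary association checks (e.g. IS/AAR vs EF measured in the same
study, therapeutic effect vs control severity) are ordinary least squares
with a two-sided t-test on the slope, via `scipy.stats.linregress`.

## Synthetic data generator

The generator draws, per study: moderators from configurable marginal
distributions; a true mean μ_i = β₀ + Σβ_j x_ij + u_i with
u_i ~ N(0, τ²_true); an arm size n_i uniform on `n_range`; and an observed
mean ȳ_i ~ N(μ_i, sd_within²/n_i) whose reported SD is `sd_within` exactly,
keeping v_i = sd²/n transparent for oracle tests (a chi-square "noisy SD"
option exists, off by default). Observed means are clamped to [0, 100] with a
logged count; clamping distorts the linear model, so simulation studies are
designed to stay in regimes where it rarely triggers (it does occur for
low-mean outcomes like IS/LV under realistic heterogeneity — the log makes
that visible). Deaths are Binomial(total, p) with p a logistic function of
configured moderator log-odds effects; records drawn with a second-stage
measurement split the phase rate as p_stage = 1 − √(1 − p) per stage so the
combined fraction stays unbiased for p. Missingness of weight/age is
completely at random at configured rates — no informative-missingness
mechanism is modelled.

Default conditions mirror a realistic large-animal MI evidence base: k = 165
comparisons per outcome; intercepts 49.8 (IS/AAR), 18.1 (IS/LV) and 39.3 (EF)
percent; τ²_true = 100 points² (between-study SD 10 points, putting I² in the
0.85–0.95 range typical of such data); per-arm SD 12 points with 4–12 animals
per arm; species roughly 74% dog / 25% pig / 1% sheep, mostly temporary LAD
occlusion by an open approach with many unreported sexes; age reported in
only ~3% of studies and weight in ~96%; peri-procedural mortality 16.7% and
post-procedural 5.2% with totals of 10–30 animals per comparison and 10% of
records carrying a second-stage measurement.

What passing tests on this generator do and do not show: the generator
matches the analysis model exactly (normal random effects, known v_i,
missingness completely at random, independent comparisons), so the tests
validate the estimation machinery — not robustness to the ways real extracted
data violate those assumptions (non-normal effects, mis-reported SDs,
correlated arms from one publication, informative missingness). The data
model records `study_id` so a clustering adjustment could be layered on, but
none is implemented.

## Numerical and design choices

- τ² search: bounded Brent on [0, 10⁴] points², tolerance 1e-10; explicit
  comparison with the τ² = 0 boundary.
- CI quantile fixed at 1.959964 everywhere.
- Reference levels default to the alphabetically first observed level; the
  shipped defaults pin conventional anchors (dog, male, permanent occlusion,
  LCX, closed, TTC) where table-style reporting makes them natural. Which
  anchors a published table actually used is often underdetermined; only the
  contrasts, which are reference-invariant here, are fully comparable.
- Follow-up stored in hours, ischemia in minutes (converters provided), so
  coefficients are directly readable against reported per-hour/per-minute
  effects.
- A DerSimonian–Laird τ² estimator exists privately as a test cross-check
  only; REML is the sole production estimator.

## Problem sizes used in the checks

The repeated-simulation checks run at 500 replicates of k = 165 for
coefficient recovery and CI coverage, 1000 replicates of k = 100 for type-I
calibration, 500 replicates of k = 100 for τ² bias, and 300 replicates of 100
binomial records for mortality pooling — sizes at which Monte-Carlo error is
comfortably below the acceptance bands while the whole suite stays fast.

## Known limitations

- No clustering of multiple comparisons from one publication.
- No model selection; the moderator set is pre-specified by the caller.
- Proportion meta-regression on the raw scale can in principle predict
  outside [0, 1]; only pooled CIs are clipped.
- The literal 1/√n weighting convention is retained for comparability but
  both conventions share the calibrated-variance machinery; neither is
  asserted to be what any given published analysis used.
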