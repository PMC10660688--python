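# Methods

## Scope and data model

The package implements a complete chain from minute-epoch wrist actigraphy
to survey-weighted associations between rest–activity rhythm (RAR)
characteristics and abnormal liver-function biomarkers. The raw unit is an
epoch record — (participant, day index, minute of day, activity value,
state ∈ {wake, sleep, nonwear, unknown}) — as produced by NHANES-style
minute files (read either from the package CSV dialect or from SAS-transport
minute files via `pandas.read_sas`, mapping SEQN/PAXDAYM/PAXSSNMP/PAXMTSM/
PAXPREDM onto the canonical schema). The wake/sleep/non-wear classifier
itself is out of scope; state labels are consumed as input.

## Quality filtering

A valid measurement day has at least 1200 minutes (20 h) of wake+sleep
data; participants enter the analysis with at least 4 valid days. Activity
is aggregated to 5-min bins anchored at midnight with half-open intervals
[5b, 5b+5) minutes. Non-wear and unknown minutes are excluded from bin
means rather than zero-filled: zero-filling would deflate the estimated
mesor and minimum. A bin with all five minutes excluded is missing and is
simply omitted from the least-squares sum (no imputation). Behavioral
covariates are the per-valid-day mean of sleep minutes and of summed
wake+sleep activity (a daily total, not a multi-day sum).

## Extended cosine model

Mean activity follows `minimum + amplitude * expit(beta * (cos((t - acrophase) * pi/12) - alpha))`.
The anti-logistic link lets the curve range from near-sinusoidal (small
`beta`) to square-wave (large `beta`); `alpha` shifts the fraction of the
day spent near the peak. Estimation is bounded nonlinear least squares over
the five parameters with a multi-start strategy, because the objective is
multimodal in acrophase: candidate starts on an acrophase grid every 2 h
crossed with `alpha ∈ {-0.6, 0, 0.6}`, initial `(minimum, amplitude)` from
the 5th percentile and the 95th−5th percentile spread, `beta` started at 2
and bounded to [0.1, 50] to avoid degenerate step fits. The three best
starts by initial RSS are polished with `scipy.optimize.least_squares`
(tolerances 1e-12) and the best solution kept; a flat-mean candidate is
always compared, so the reported RSS never exceeds the null RSS and the
flat-model limit (amplitude → 0) is exact.

Reported quantities are curve-level: `minimum` is the fitted nadir,
`amplitude` the peak-minus-nadir difference (for finite `beta` this is
slightly below the raw amplitude parameter, since the logistic never
reaches 0 or 1), mesor = minimum + amplitude/2 exactly by construction, and
acrophase the argmax of the fitted curve on a 1-min grid (tie-broken to the
earliest time; for this symmetric link it coincides with the cosine peak
parameter up to grid resolution). The pseudo-F statistic uses a flat-mean
null with k−1 = 4 numerator and n−5 denominator degrees of freedom; the df
convention matters little downstream because all analyses use quintile
ranks of F, which are invariant to it. A constant series yields F = 0; a
perfect fit yields +inf.

Requirements: at least 576 non-missing 5-min observations (two days'
worth) to fit. Optimizer failure after all restarts flags the fit
non-converged, and non-converged fits are excluded downstream.

## Nonparametric metrics

IS and IV are computed on 60-min means derived from the 5-min bins (the
dominant convention; the bin width is a keyword argument).

* IS = (variance of hour-of-day means about the grand mean) / (total
  variance), using the hours actually present; 1 for a perfectly repeating
  daily pattern, ≈ 1/d for d days of white noise.
* IV = (mean squared successive difference) / variance, with differences
  taken only between truly adjacent hours — never across gaps created by
  missing hours or missing days, which would otherwise inject spurious
  fragmentation. White noise gives IV ≈ 2, a slow sinusoid ≪ 1, an
  alternating series 4. Zero-variance series give a missing value with a
  warning.

The L5 midpoint is computed on the across-valid-days average 288-bin
profile (not per-day-then-averaged): all 5-h windows at 5-min steps with
midnight wraparound are scanned, the lowest-mean window wins, ties to the
earliest start. Profiles more than 50% missing return a missing metric.
The night-shift/unconventional-timing proxy flags a participant whose L5
midpoint lies strictly more than two circular standard deviations
(sqrt(−2 ln R), mapped to hours) from the cohort circular median; circular
statistics are used because clock-time SDs are distorted by the midnight
wrap, and the strict inequality means an all-identical cohort flags
nobody. Cohorts below 10 are refused as unstable.

## Scoring

Quintiles are survey-weighted: cut-points at the weighted 20/40/60/80th
percentiles of the weighted CDF (left-continuous inverse), values equal to
a cut-point assigned to the lower quintile — fixed for reproducibility; an
unweighted switch exists for sensitivity. The presumed lowest-risk
reference quintile is Q1 for acrophase and IV and Q5 for pseudo-F,
amplitude, mesor, amplitude:mesor and IS. The impaired-rhythmicity
composite counts membership of the least-healthy quintile among pseudo-F,
amplitude, mesor (Q1) and acrophase (Q5), capped at 3 ("3+"). Biomarker
abnormality uses strict sex-specific inequalities (ALT > 47/30 IU/L M/F,
AST > 33, ALP > 113, GGT > 65/36 M/F, albumin < 3.7 g/dL, bilirubin > 1.3
mg/dL); the abnormal composite is the count of abnormal markers capped at 3.

## Eligibility cascade

The analytic sample drops, in order: age < 20; age 80+ (top-coded ages);
pregnancy; no actigraphy; < 4 valid days; missing all six biomarkers. The
ledger records (label, excluded, remaining) per stage and validates the
arithmetic; attribution is order-dependent but the final set is the
intersection of the inclusion predicates. Missing-all-six is the exclusion
criterion; each biomarker's model further restricts to complete cases for
that outcome and the model's covariates.

## Survey-weighted estimation

Point estimates solve weighted estimating equations (pseudo-ML):
statsmodels GLM (binomial), WLS (on natural-log levels), and the
proportional-odds likelihood of statsmodels' OrderedModel maximized under
weights with scipy. Variance is the survey sandwich `A⁻¹ B A⁻¹` with
`A = Σ w_i H_i` and `B = (n/(n−p)) Σ w_i² s_i s_iᵀ` — weights enter the
meat squared (importance weights, not frequency weights), with an
HC1-style small-sample factor. 95% CIs use ±1.96·SE. Quasi-separation is
detected (fitted probabilities at machine bounds or |coef| > 15) and
flagged rather than silently diverging. With unit weights all three
families reproduce the ordinary unweighted fits; the logistic sandwich was
cross-checked against R's `glm` + `sandwich::vcovHC(type="HC1")` in the
test suite.

Weights-only estimation is deliberate: the design intent is a weighted
analysis without sampling strata/PSU information, so the sandwich variance
is model-robust but not fully design-based.

* **Trend tests** refit with the quintile index as one continuous covariate
  and use the robust Wald p; this is calibrated under variable weights and
  invariant to affine recoding of the index.
* **Interaction tests** are working likelihood-ratio tests on the weighted
  log-likelihood. A naive weighted LRT is anticonservative by roughly
  E[w²]/E[w]², so the second-order (Satterthwaite) Rao–Scott correction is
  applied: the statistic is divided by `δ̄(1+cv²)` and referred to χ² with
  `df/(1+cv²)` effective degrees of freedom, where δ are the eigenvalues of
  the product of the tested block's model-based information and its
  sandwich covariance. With unit weights this reduces to the ordinary LRT;
  simulations in the test suite show ~5% type-I error at n = 4000 with
  lognormal(σ = 0.5) weights.
* The ordinal model collapses outcome levels absent from the data with a
  warning and reduces exactly to the binary logistic fit for two levels.

Adjustment sets: model1 = age + gender; model2 (main) adds race/ethnicity,
education, income, marital status, smoking, alcohol and hepatitis B/C/E;
model3 = model2 + diabetes; model4 = model2 + BMI category; the behavioral
sensitivity set = model2 + total activity + sleep duration. Complete-case
per model; per-cell n is recorded. Stratified runs refit within strata and
flag small strata; the shift-worker sensitivity refits after removing
flagged participants and reports the count removed.

## Synthetic data generator

The generator defines the validation conditions. Minute activity is the
extended cosine mean curve plus additive Gaussian noise truncated at zero —
the activity-count noise distribution is a stand-in choice; real MIMS
counts are right-skewed and heteroskedastic, so passing recovery tests
demonstrate estimator correctness under the stated noise model, not
robustness to every feature of real accelerometry. Default truth: minimum
10, amplitude 100, acrophase 14 h, alpha 0, beta 8, noise SD 5, 7 days —
an amplitude-to-noise ratio of 20, typical of a clearly rhythmic wearer;
recovery studies draw amplitude uniform in [40, 160] with noise up to half
the amplitude (ratio ≥ 2). The sleep window (default 480 min) is centred
on the curve nadir, so sleep-epoch activity is near the minimum and sleep
duration is recoverable; non-wear blocks carry missing activity and may
not overlap each other or the sleep window (validation error). One master
seed; per-participant streams derive via
`SeedSequence([master, 1 + index])` so outputs are byte-identical under
any ordering or parallelism.

The cohort layer draws categorical covariates from configurable marginals
(defaults loosely matching a US adult examination survey), lognormal
weights normalized to mean 1 (σ = 0.5 by default — positive and
right-skewed like examination weights), an age structure with a minor slab
and a top-coded 80+ slab, pregnancy concentrated among women 20–44, and
the availability flags the cascade consumes. Biomarker abnormality is
drawn from a logit model with configurable per-quintile log-odds and
covariate effects; continuous levels are then sampled on the correct side
of the sex-specific cut-off (exponential tails around the threshold), so
flags recomputed from levels match the drawn statuses exactly. The
generator does not emulate multistage sampling strata/PSUs (weights only)
nor the raw 80 Hz signal or the sleep classifier.

## Validation problem sizes

Chosen as the package's standard desk-scale validation settings: 200
simulated 7-day participants for cosine recovery (median absolute
acrophase error ≤ 0.25 h, median relative amplitude error ≤ 10%); 500
replicates at n = 4000 for odds-ratio bias (±0.05 on the log scale) and CI
coverage (93–97%); 2000 replicates at n = 4000 for trend and interaction
type-I error (4–6%); 500 replicates of 7×24 Gaussian noise for the IS and
IV limits (1/7 ± 0.02 and 2 ± 0.1). Published full-scale headline odds
ratios from the motivating cohort would require the multi-gigabyte public
accelerometer files and are not part of the desk-scale validation; the
readers for their dialects are provided.

## Known limitations

* The Gaussian activity-noise model and exponential level tails are
  conveniences, not fitted distributions.
* The working LRT is approximate under weights even after correction;
  strongly informative weights correlated with covariates were not
  simulated.
* The proportional-odds fit reports cut-points in the internal
  transformed parametrization (first threshold, then log-increments);
  exposure coefficients and their sandwich SEs are unaffected.
* L5 midpoints on near-square-wave rhythms with broad flat troughs are
  noise-located within the trough; the shift-work rule is therefore
  calibrated for cohorts with a dominant diurnal mode.
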