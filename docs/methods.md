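# Methods

This note documents the statistical machinery, the synthetic-cohort model
behind the default configuration, the numerical choices, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The validation problem

Four published dementia risk models are scored on a cohort of
community-dwelling adults aged 55+ with a right-censored time-to-dementia
outcome, and compared on discrimination (Harrell's C at 2/5/10/15-year
horizons, with follow-up truncated at each horizon) and calibration
(intercept/slope of predicted vs observed 10-year risk, plus recalibration).
Each model is also evaluated as *age-only* (its age component) and
*without-age* (the remainder), an exact decomposition of the full score.
Dementia-free death is treated as censoring throughout — there is no
competing-risk estimand — so all "risks" are cause-specific quantities that
overstate real-world absolute risk in an elderly population; this mirrors
the validation design the package reproduces and is flagged as a limitation,
not a recommendation.

## Risk-score implementations

Point tables and the DRS coefficients are shipped in
`src/demrisk/config/score_tables.yaml` and can be overridden without code
changes. Conventions worth knowing:

- **Strict inequalities.** Category boundaries follow the printed
  inequalities strictly (CAIDE hypertension is SBP > 140, not ≥; obesity
  BMI > 30). Ties go to the lower-point category. CAIDE education is
  floored to whole years before banding so the printed 0–6 / 7–9 / ≥10
  bands are exhaustive.
- **BDSI age anchor.** The instrument specifies "1 point per year" without
  an origin; we anchor 0 points at age 65 (the lower design age). Any
  affine shift leaves every rank-based metric unchanged; the anchor affects
  reporting only. Outside 65–79 the same linear rule is extrapolated only
  on request (the whole-cohort analysis turns it on and logs it).
- **ANU-ADRI age-by-sex grid.** Only the endpoints of the published grid
  are printed (0 points, men < 65; 41 points, women ≥ 90). The bundled
  interior values are a *synthetic monotone interpolation* over 5-year
  bands, clearly marked in the config file and replaceable. The education
  points are implemented exactly as printed (8–11 y: 3; > 11 y: 6) although
  the direction is surprising for a protective factor; override via config
  if desired.
- **ANU-ADRI adaptations.** The `rotterdam` adaptation (default) omits
  pesticide exposure and cognitive activity and derives social engagement
  from a three-domain composite (living with a partner, married, lonely;
  adverse count 0–3 → high / medium-high / medium-low / low). The
  `original` adaptation requires the two extra items passed explicitly.
  Physical-activity bands for the score are MET-hour thresholds
  (medium ≥ 30, high ≥ 90 MET-h/week), a documented approximation of the
  frequency-based instrument bands.
- **CAIDE inactivity.** Active means ≥ 40 min/week at MET ≥ 4, evaluated on
  the `active_minutes_met4` field; when only total leisure MET-hours are
  known, a configurable fallback threshold (2.67 MET-h/week ≡ 40 min at
  MET 4) stands in. Total MET-hours cannot resolve intensity, so the
  fallback is an approximation and the direct minutes field is preferred.
- **DRS.** Hypertension is SBP > 140 mmHg or current antihypertensive
  treatment; the depression term fires on depressive symptoms or
  antidepressant use; the deprivation quintile is emulated from the same
  three-domain household composite (default mapping {0→1, 1→2, 2→4, 3→5};
  quintile 3 is reachable only through a user-supplied mapping). The
  printed 60–79 equation is bundled; an 80–95 equation can be registered,
  otherwise ages ≥ 80 fall back to the young equation with a logged
  warning. The unassigned printed band [79, 80) goes to the young equation
  for continuity with its centering. The calendar-year term uses each
  participant's baseline examination year.

## Discrimination

Harrell's C uses the standard conventions: a pair is comparable iff the
member with the strictly shorter time had an event (time ties are not
comparable); predictor ties are credited ½. Pair counting is exact (a
compiled O(events × n) kernel), verified in tests against an independent
brute-force enumeration. Confidence intervals are a seedable nonparametric
bootstrap (percentile, 500 replicates by default; the pipeline default is
200, and 0 skips the interval). A constant predictor returns a degenerate
flag with C = 0.5 — this is how the CAIDE age-only variant surfaces in a
55+ cohort, where everyone occupies the top CAIDE age band.

## Calibration and recalibration

The binary outcome at horizon *h* is "dementia by *h*"; participants
censored dementia-free before *h* are excluded (the simplest defensible
choice; a Kaplan–Meier-based per-decile observed risk is available as a
censoring-robust alternative for plot data). Slope is the coefficient of
logit(p̂) in a logistic regression of the outcome; intercept is the same
regression with the slope fixed at 1 (offset parameterisation). Deciles of
predicted risk with Wilson binomial CIs supply the plot data.

Recalibration: for logistic-type models, the intercept shift δ solves
mean(expit(logit(p̂) + δ)) = observed event proportion (Brent's method,
tolerance 1e-13, so the defining identity holds to ~1e-10). For Cox-type
models, S̄(h) is the validation Kaplan–Meier estimate and updated risks are
1 − S̄(h)^exp(LP − mean LP). Note the Cox update calibrates at the *mean
linear predictor*, not in the large: with a high-variance LP the mean
updated risk exceeds the observed proportion by Jensen's inequality, which
is a property of the procedure, not a bug.

C-statistics across imputations are pooled by Rubin's rules on the raw
scale (bootstrap SEs as within-imputation variance); with intervals
disabled the pooled estimate is the plain mean.

## Synthetic cohort

The generator emulates a two-wave Dutch elderly cohort: an original wave
(n = 3983, older, mean age 72.2, SD 7.0) and an extended wave (n = 2684,
younger, 64.6/7.9), ages drawn from normals truncated below at 55 whose
*post-truncation* moments match those targets (the pre-truncation
parameters are solved from the closed-form truncated-normal moments via a
one-dimensional root find). Administrative censoring is uniform per wave
(original 16–18 y, extended 14–15 y, i.e. enrollment windows 1997–1999 and
2000–2001 against an administrative end of study); the baseline calendar
year used by the DRS is derived from the same draw.

Covariate marginals per wave come from the published baseline table.
Covariates are age-linked: continuous means shift linearly in age and
binary prevalences logistically, with slopes derived mechanically as the
between-wave contrast divided by the between-wave age gap (the two waves
sample one source population at different ages, so the contrast is the
natural slope estimate); intercepts are re-anchored on the realised ages so
wave marginals match their targets exactly in expectation. Categorical
covariates interpolate the two wave probability vectors log-linearly in
age. Leisure activity is log-normal (matched to the published medians and
interquartile ratios) and generated jointly with MET≥4 minutes/week
(log-scale correlation 0.6); the minutes level is a design choice placing
roughly one participant in eight below the 40-min inactivity cutoff.
Household items without a published margin (marital status, living
arrangement, loneliness, antidepressant use, heavy drinking) use typical
Dutch elderly-population values, stated in the config.

Outcomes follow cause-specific Gompertz hazards in attained age,
h(t) = rate · exp(shape · (age + t − 70)), drawn by inverse transform of
the closed-form cumulative hazard. Defaults: dementia rate 0.00465/y at
attained age 70 with shape 0.115/y (incidence doubling every ~6 years);
dementia-free death rate 0.022/y with shape 0.092/y. The two rates were
calibrated by simulation so the default cohort reproduces the published
validation-sample summaries — crude dementia incidence ≈ 11.5 per 1000
person-years and median observed follow-up ≈ 13.2 years — and then frozen.
Per-covariate log-hazard terms default to zero (age carries all signal,
making "age-only ≈ full model" the ground truth of the default scenario);
they are config switches for power studies, and the test suite
demonstrates that the pipeline detects C(full) > C(age-only) when real
covariate effects are switched on.

Missingness is MCAR per covariate and wave, at the published item
non-response rates; head trauma and fish intake are structurally missing
for the entire extended wave (reproducing overall missing fractions of
≈ 41% and ≈ 48%). Outcome fields, age and sex are never masked.

`true_risk` is the closed-form cause-specific 10-year (or any-horizon)
dementia risk implied by the configured hazard — an oracle for
self-validation. The self-validation test runs with the death hazard
disabled: the oracle deliberately ignores death, so with deaths on, the
exclusion-based binary calibration outcome is upward-biased (conditioning
on surviving the horizon selects against high-hazard person-time) and
would test the estimand mismatch rather than the machinery.

### What the generator does *not* emulate

Only marginals are matched: the joint covariate structure is induced
entirely by the shared age link, so covariate–covariate correlations at
fixed age are absent. The age distributions are truncated normals, not the
real right-skewed enrollment distributions — the fraction under 65 lands
near 34% rather than the published 37% even with per-wave moments matched
exactly, a shape limitation noted in the tests. Missingness is MCAR only
(the real mechanism is unknown; MCAR suffices to exercise the imputation
stage), and the dementia-ascertainment process is not modelled at all:
event times are the latent hazard draws. Consequently, passing tests show
the *machinery* is correct and the cohort-level summaries are reproduced;
they do not certify performance numbers on the real restricted data.

## Multiple imputation

Chained equations, 10 cycles by default, initialised by random draws from
the observed margins; each variable's model includes all other covariates
(one-hot for categoricals), the event indicator, and the Nelson–Aalen
cumulative hazard of follow-up time. Continuous variables use predictive
mean matching with a Bayesian coefficient draw (ridge-stabilised normal
equations, 5 donors); binary and categorical variables use logistic /
multinomial draws at the maximum-likelihood fit, which slightly understates
between-imputation variance — a known simplification. "5-fold multiple
imputation" is read as m = 5 completed datasets. Wave-structured variables
are imputed from the wave in which they were observed. Everything is
deterministic given the seed, and observed values and outcomes are never
altered.

## Problem sizes and numerical choices

The test suite exercises the full default cohort (n = 6667) where the check
concerns generator calibration or the age-dominance headline, and scaled
cohorts (n ≈ 200–5000) elsewhere; brute-force concordance oracles run at
n ≤ 200 where exhaustive enumeration is exact and fast. Bootstrap
replicates default to 500 (standalone) / 200 (pipeline). Predictions are
clipped to (1e-12, 1 − 1e-12) before logit transforms. Root finds use
Brent's method on bracketed intervals. Degenerate inputs (no events,
constant predictors, all-identical outcomes, empty strata) raise typed
errors or carry explicit flags rather than returning silent numbers.
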