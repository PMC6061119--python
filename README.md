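# demrisk

Head-to-head external validation of four published dementia risk prediction
models — CAIDE, the Brief Dementia Screening Indicator (BDSI), the ANU
Alzheimer's Disease Risk Index (ANU-ADRI), and the Dementia Risk Score
(DRS) — on elderly, community-dwelling cohorts, together with a seedable
synthetic-cohort generator so the entire pipeline runs at desk scale without
access to any restricted study data.

It is written for epidemiologists and biostatisticians who want to (a) score
a cohort with these instruments exactly as published, (b) quantify
discrimination and calibration of the resulting predictions for censored
time-to-dementia outcomes, and (c) ask the key substantive question: *how
much predictive value do the models add beyond age alone?*

## What it computes

**Risk scores.** Each scorer implements the published point table or
regression equation verbatim, and decomposes every total into an age
component and the remainder, so that `age_only + without_age = full` exactly.
The DRS is a Cox-type equation whose predicted 5-year risk is
`100 × [1 − S₀^exp(P)]` with baseline survival `S₀ = 0.9969` and `P` the
printed linear predictor. Cohort-specific adaptations (a MET-based physical
inactivity rule for CAIDE, a three-domain social-engagement composite, an
emulated area-deprivation quintile for the DRS, BDSI age extrapolation at
1 point/year, DRS age-band stitching) are implemented and logged per run.

**Discrimination.** Harrell's concordance C for right-censored data: over
comparable pairs (the member with the shorter follow-up had the event), the
fraction where that member also has the higher predictor, predictor ties
credited ½, with a seedable bootstrap percentile CI. Follow-up is truncated
at prediction horizons of 2/5/10/15 years.

**Calibration and recalibration.** Calibration slope (coefficient of
logit(p̂) in a logistic regression of event-by-horizon) and intercept
(same regression with slope fixed at 1), decile calibration-plot data, an
intercept update for logistic models, and the Cox-type update
`risk = 1 − S̄(h)^exp(LP − mean LP)` with `S̄(h)` the validation Kaplan–Meier
estimate.

**Missing data.** Chained-equations multiple imputation (predictive mean
matching / logistic / multinomial draws; imputation models include all
covariates, the event indicator and the cumulative-hazard transform of
follow-up time), with Rubin's rules for pooling.

**Synthetic cohorts.** A two-wave elderly cohort (n = 6667 by default:
3983 + 2684) with per-wave covariate marginals matched to the published
baseline table, covariates linked to age through the between-wave contrast,
Gompertz hazards in attained age for dementia and dementia-free death
(death treated as censoring, as in the validation design), per-wave
administrative censoring, and wave-structured missingness. Defaults are
calibrated to the published cohort summaries: crude dementia incidence
≈ 11.5 per 1000 person-years and median follow-up ≈ 13.2 years.

## Worked example

Score one 70-year-old woman (former smoker, treated hypertension, diabetes,
9 years of education, BMI 28, cholesterol 6.8 mmol/L, largely inactive):

```python
from demrisk import scores
from demrisk.schema import Participant

p = Participant(id="example", wave="original", age=70.0, sex="female",
                education_years=9.0, sbp=150.0, bmi=28.0,
                total_cholesterol=6.8, physical_activity_met_hours=30.0,
                active_minutes_met4=20.0, diabetes=True, smoking="former",
                alcohol_user=True, heavy_drinking=False, stroke=False,
                tia=False, atrial_fibrillation=False, head_trauma=False,
                depressive_symptoms=False, needs_help_finances_medications=False,
                living_with_partner=True, married=True, lonely=False,
                fish_servings_week="0.26-2.0", uses_antihypertensives=True,
                uses_anxiolytics=False, uses_aspirin=False,
                uses_antidepressants=False, uses_nsaids=False,
                calendar_year=1998.0)
for model in ("caide", "bdsi", "anu_adri", "drs"):
    c = scores.score_participant(model, p)
    print(model, c.total, c.age_points, c.non_age_points, c.predicted_risk)
```

```
caide     total=11.0000 (age 4.0000 + other 7.0000)
bdsi      total=17.0000 (age 5.0000 + other 12.0000)
anu_adri  total=18.0000 (age 14.0000 + other 4.0000)
drs       total=1.0466 (age 0.8535 + other 0.1932), 5-y risk 0.88%
```

She collects 11/15 CAIDE points (4 for age, 2 each for SBP > 140, BMI is
not > 30 so none there, cholesterol > 6.5, education 7–9 years, 1 for
inactivity), 17 BDSI points (5 for age above 65, 9 for < 12 years of
education, 3 for diabetes), and a DRS linear predictor of 1.05, i.e. a
predicted 5-year dementia risk of 0.88%.

Validate models on the default simulated cohort (n = 6667), with multiple
imputation of the injected missingness and bootstrap CIs:

```python
from demrisk import simulate, pipeline
cohort = simulate.generate_cohort(seed=1)          # default n = 6667
report = pipeline.run_validation(cohort, models=("bdsi", "drs"),
                                 horizons=(5, 10), m=5, seed=1,
                                 n_bootstrap=100)
```

```
bdsi  full        h=10.0 C=0.702 (0.680-0.724)  events=527
bdsi  age_only    h=10.0 C=0.731 (0.711-0.751)  events=527
bdsi  without_age h=10.0 C=0.597 (0.573-0.620)  events=527
drs   full        h=10.0 C=0.717 (0.697-0.737)  events=527
drs   age_only    h=10.0 C=0.731 (0.711-0.751)  events=527
drs   without_age h=10.0 C=0.511 (0.488-0.535)  events=527
```

The age-only variants discriminate essentially as well as the full models,
and the models stripped of age perform far worse — age carries nearly all
of the predictive signal in an elderly cohort. (CAIDE's age-only variant is
reported as degenerate: everyone aged 55+ sits in its top age band.)

The same run is available from the shell:

```sh
demrisk simulate-cohort --seed 1 --out cohort.csv
demrisk validate --cohort cohort.csv --models bdsi,anu-adri,drs \
    --horizons 2,5,10,15 --m 5 --seed 1 --out report/
demrisk validate --cohort cohort.csv --sensitivity age80 --out strata/
```

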