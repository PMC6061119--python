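"""The four published dementia risk models, exactly as printed.

Implements the CAIDE point score, the Brief Dementia Screening Indicator
(BDSI), the ANU Alzheimer's Disease Risk Index (ANU-ADRI) and the Dementia
Risk Score (DRS, a Cox-type equation with an absolute 5-year risk transform),
together with the cohort-specific adaptations needed to apply them to an
elderly Dutch population sample:

* CAIDE physical inactivity from a minutes-per-week-at-MET>=4 rule (with a
  documented MET-hours fallback when only total leisure activity is known);
* ANU-ADRI social engagement reduced from five to three domains (living
  status, marital status, loneliness);
* the DRS area-deprivation quintile emulated from the same three-domain
  household composite;
* BDSI age extrapolation outside its 65-79 design range (1 point/year), and
  DRS equation stitching across its two age bands.

Every scorer returns :class:`ScoreComponents`, splitting the total into an
age component and the remainder, so age-only / without-age model variants
are exact decompositions of the full score.

Category boundaries follow the printed inequalities strictly (hypertension
means SBP > 140, obesity BMI > 30 for CAIDE); ties go to the lower-point
category.  Point tables and the DRS coefficients ship as a structured YAML
file so supplementary-only coefficients (e.g. a DRS 80-95 equation) can be
supplied without code changes.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .schema import MissingInputError, Participant, participant_from_row

MODELS = ("caide", "bdsi", "anu_adri", "drs")
VARIANTS = ("full", "age_only", "without_age")


class DesignRangeError(ValueError):
    """Participant outside a model's design age range with extrapolation off."""


@dataclass
class ScoreComponents:
    """A model's total score split into age and non-age parts.

    ``total`` is in score points, except for the DRS where it is the linear
    predictor.  ``predicted_risk`` is an absolute probability in [0, 1],
    defined for the DRS (and for CAIDE when a score-to-risk mapping is
    configured), ``None`` otherwise.
    """

    model: str
    total: float
    age_points: float
    non_age_points: float
    predicted_risk: Optional[float] = None

    def variant(self, name: str) -> float:
        if name == "full":
            return self.total
        if name == "age_only":
            return self.age_points
        if name == "without_age":
            return self.non_age_points
        raise ValueError(f"unknown variant '{name}'")


@lru_cache(maxsize=1)
def _default_tables() -> dict:
    with resources.files("demrisk.config").joinpath("score_tables.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_score_tables(path=None) -> dict:
    """Load the score definition tables (the packaged defaults, or a user
    YAML file with the same structure)."""
    if path is None:
        return copy.deepcopy(_default_tables())
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


# --------------------------------------------------------------------------
# CAIDE
# --------------------------------------------------------------------------


def _is_physically_active(p: Participant, t: dict) -> bool:
    """Active means >= 40 minutes/week of exercise at MET intensity >= 4.

    If only total leisure MET-hours are known, a configurable threshold
    (default 2.67 MET-hours/week, i.e. 40 minutes at MET 4) stands in -- an
    approximation, since total MET-hours do not resolve intensity.
    """
    minutes = p.active_minutes_met4
    if minutes is not None and not (isinstance(minutes, float) and math.isnan(minutes)):
        return minutes >= t["active_minutes_met4_threshold"]
    met_hours = p.require("physical_activity_met_hours")
    return met_hours >= t["met_hours_fallback_threshold"]


def caide_score(p: Participant, tables: dict | None = None) -> ScoreComponents:
    """CAIDE midlife dementia risk score (0-15 points)."""
    t = (tables or _default_tables())["caide"]
    age, sex, education, sbp, bmi, chol = p.require(
        "age", "sex", "education_years", "sbp", "bmi", "total_cholesterol"
    )
    a = t["age"]
    if age < a["mid_min"]:
        age_points = 0
    elif age <= a["mid_max"]:
        age_points = a["mid"]
    else:
        age_points = a["old"]

    e = t["education_bands"]
    edu = math.floor(education)  # whole years before banding
    if edu <= e["low_max"]:
        edu_points = e["low"]
    elif edu <= e["mid_max"]:
        edu_points = e["mid"]
    else:
        edu_points = e["high"]

    non_age = (
        (t["sex_male"] if sex == "male" else 0)
        + edu_points
        + (t["sbp_over_140"] if sbp > 140 else 0)
        + (t["bmi_over_30"] if bmi > 30 else 0)
        + (t["cholesterol_over_6_5"] if chol > 6.5 else 0)
        + (0 if _is_physically_active(p, t) else t["inactive"])
    )
    return ScoreComponents("caide", age_points + non_age, age_points, non_age)


def caide_predicted_risk(total: float, risk_table: dict) -> float:
    """Absolute dementia risk from a configured CAIDE score-to-risk mapping
    (a supplementary table; none is bundled).  The mapping is a dict of
    ``score: probability``; scores above the largest key use its value."""
    keys = sorted(risk_table)
    for k in reversed(keys):
        if total >= k:
            return float(risk_table[k])
    return float(risk_table[keys[0]])


# --------------------------------------------------------------------------
# BDSI
# --------------------------------------------------------------------------


def bdsi_score(p: Participant, extrapolate_age: bool = False,
               tables: dict | None = None) -> ScoreComponents:
    """Brief Dementia Screening Indicator.

    Age contributes 1 point per year above the lower design age (65); outside
    the 65-79 design range the same linear rule is extrapolated only when
    ``extrapolate_age`` is set, otherwise :class:`DesignRangeError` is raised.
    The anchor at 65 is a reporting convention: any affine shift of the age
    component leaves rank-based metrics unchanged.
    """
    t = (tables or _default_tables())["bdsi"]
    age, education, bmi, diabetes, stroke, needs_help, depressive = p.require(
        "age", "education_years", "bmi", "diabetes", "stroke",
        "needs_help_finances_medications", "depressive_symptoms",
    )
    lo, hi = t["design_age_range"]
    if not extrapolate_age and not lo <= age <= hi:
        raise DesignRangeError(
            f"age {age:.1f} outside BDSI design range [{lo}, {hi}]"
        )
    age_points = (age - t["age_anchor"]) * 1.0
    non_age = (
        (t["education_under_12"] if education < 12 else 0)
        + (t["bmi_under_18_5"] if bmi < 18.5 else 0)
        + (t["diabetes"] if diabetes else 0)
        + (t["stroke"] if stroke else 0)
        + (t["needs_help"] if needs_help else 0)
        + (t["depressive_symptoms"] if depressive else 0)
    )
    return ScoreComponents("bdsi", age_points + non_age, age_points, non_age)


# --------------------------------------------------------------------------
# ANU-ADRI
# --------------------------------------------------------------------------


def social_engagement_from_domains(living_with_partner: bool, married: bool,
                                   lonely: bool) -> str:
    """Three-domain social-engagement composite: count of adverse states
    (not living with a partner, unmarried, lonely) mapped to the four
    instrument levels."""
    adverse = int(not living_with_partner) + int(not married) + int(lonely)
    return ("high", "medium_high", "medium_low", "low")[adverse]


def anu_adri_score(p: Participant, adaptation: str = "rotterdam",
                   tables: dict | None = None,
                   pesticide_exposure: bool | None = None,
                   cognitive_activity: str | None = None) -> ScoreComponents:
    """ANU Alzheimer's Disease Risk Index.

    ``adaptation='original'`` scores the full 15-item instrument and requires
    the pesticide-exposure and cognitive-activity items (passed explicitly,
    as they sit outside the cohort schema).  ``'rotterdam'`` drops those two
    items and derives social engagement from the three-domain composite.

    The education points are implemented exactly as printed in the source
    point table (8-11 years: 3, > 11 years: 6) even though the direction is
    surprising for a protective factor; override via ``tables`` if needed.
    """
    t = (tables or _default_tables())["anu_adri"]
    age, sex, education, chol, diabetes, head_trauma, depressive = p.require(
        "age", "sex", "education_years", "total_cholesterol", "diabetes",
        "head_trauma", "depressive_symptoms",
    )
    smoking, alcohol_user, bmi, fish, met_hours = p.require(
        "smoking", "alcohol_user", "bmi", "fish_servings_week",
        "physical_activity_met_hours",
    )

    edges = t["age_band_edges"]
    band = int(np.searchsorted(edges, age, side="right"))
    grid = t["age_points_female"] if sex == "female" else t["age_points_male"]
    age_points = grid[band]

    e = t["education"]
    if education > e["mid_max"]:
        edu_points = e["high"]
    elif education >= e["mid_min"]:
        edu_points = e["mid"]
    else:
        edu_points = 0

    if adaptation == "rotterdam":
        lwp, married, lonely = p.require("living_with_partner", "married", "lonely")
        social = social_engagement_from_domains(lwp, married, lonely)
        extra = 0
    elif adaptation == "original":
        if pesticide_exposure is None or cognitive_activity is None:
            raise MissingInputError(
                "pesticide_exposure/cognitive_activity",
                "the original ANU-ADRI needs the pesticide-exposure and "
                "cognitive-activity items",
            )
        social = p.require("social_engagement")
        extra = (t["pesticide_exposure"] if pesticide_exposure else 0) \
            + t["cognitive_activity"][cognitive_activity]
    else:
        raise ValueError(f"unknown adaptation '{adaptation}'")

    heavy = p.heavy_drinking if p.heavy_drinking is not None else False
    alcohol_points = t["alcohol_light_moderate"] if (alcohol_user and not heavy) else 0

    if met_hours >= t["activity_met_hours_high"]:
        activity_points = t["physical_activity"]["high"]
    elif met_hours >= t["activity_met_hours_medium"]:
        activity_points = t["physical_activity"]["medium"]
    else:
        activity_points = 0

    if bmi >= 30:
        bmi_points = t["bmi_obese"]
    elif bmi >= 25:
        bmi_points = t["bmi_overweight"]
    else:
        bmi_points = 0

    non_age = (
        edu_points
        + (t["diabetes"] if diabetes else 0)
        + (t["head_trauma"] if head_trauma else 0)
        + (t["depressive_symptoms"] if depressive else 0)
        + (t["high_cholesterol"] if chol > t["cholesterol_threshold"] else 0)
        + t["social_engagement"][social]
        + t["smoking"][smoking]
        + alcohol_points
        + activity_points
        + bmi_points
        + t["fish"][fish]
        + extra
    )
    return ScoreComponents("anu_adri", age_points + non_age, age_points, non_age)


# --------------------------------------------------------------------------
# DRS
# --------------------------------------------------------------------------


@dataclass
class DrsEquation:
    """One DRS Cox-type equation: centering constants, coefficients, and a
    5-year baseline survival."""

    age_band: str
    age_center: float
    bmi_center: float
    year_center: float
    baseline_survival: float
    coefficients: dict

    def validate(self):
        if not 0 < self.baseline_survival < 1:
            raise ValueError("baseline survival must lie in (0, 1)")
        for k, v in self.coefficients.items():
            if not np.isfinite(v):
                raise ValueError(f"DRS coefficient '{k}' must be finite")


def default_drs_registry(tables: dict | None = None) -> dict:
    """Registry of DRS equations by age band.  Only the published 60-79
    equation is bundled; an 80-95 equation (supplementary-only) can be added
    under the key ``'80-95'``."""
    t = (tables or _default_tables())["drs"]
    young = DrsEquation(**t["young"])
    young.validate()
    return {"60-79": young}


def deprivation_quintile(living_with_partner, married, lonely,
                         mapping: dict | None = None) -> int:
    """Emulated area-deprivation quintile from the household composite.

    The count of adverse states (0-3) maps monotonically onto quintiles via
    a configurable table, by default {0: 1, 1: 2, 2: 4, 3: 5} (quintile 3 is
    reserved for intermediate weighting schemes).
    """
    for name, value in (("living_with_partner", living_with_partner),
                        ("married", married), ("lonely", lonely)):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingInputError(name)
    if mapping is None:
        mapping = _default_tables()["drs"]["deprivation_quintile_map"]
    adverse = int(not living_with_partner) + int(not married) + int(lonely)
    return int(mapping[adverse])


def drs_select_equation(age: float, registry: dict) -> DrsEquation:
    """Pick the DRS equation for a participant's age: below 80 the 60-79
    equation, 80 and over the 80-95 equation when configured (falling back to
    the young equation with a warning)."""
    if not registry:
        raise ValueError("empty DRS equation registry")
    if age < 80:
        return registry["60-79"]
    old = registry.get("80-95")
    if old is not None:
        return old
    warnings.warn(
        "no 80-95 DRS equation configured; using the 60-79 equation "
        f"for age {age:.1f}", stacklevel=2,
    )
    return registry["60-79"]


def drs_linear_predictor(p: Participant, eq: DrsEquation,
                         tables: dict | None = None) -> ScoreComponents:
    """Evaluate the printed DRS linear predictor for one participant.

    Hypertension is SBP > 140 mmHg or current antihypertensive treatment;
    the depression term is depressive symptoms and/or antidepressant use;
    the calendar-year term uses the participant's baseline examination year.
    Ages below 60 (outside both design bands) are computed with a warning.
    """
    t = (tables or _default_tables())["drs"]
    c = eq.coefficients
    age, bmi, sex, sbp, antihyp, year = p.require(
        "age", "bmi", "sex", "sbp", "uses_antihypertensives", "calendar_year"
    )
    smoking, heavy, depressive, antidep, aspirin = p.require(
        "smoking", "heavy_drinking", "depressive_symptoms",
        "uses_antidepressants", "uses_aspirin",
    )
    stroke, tia, af, diabetes = p.require(
        "stroke", "tia", "atrial_fibrillation", "diabetes"
    )
    if age < 60:
        warnings.warn(
            f"age {age:.1f} below both DRS design bands; computed anyway",
            stacklevel=2,
        )
    quintile = deprivation_quintile(
        p.living_with_partner, p.married, p.lonely,
        t.get("deprivation_quintile_map"),
    )

    da = age - eq.age_center
    db = bmi - eq.bmi_center
    age_part = c["age"] * da + c["age_sq"] * da * da

    hypertension = sbp > t["hypertension_sbp_threshold"] or bool(antihyp)
    anxiety = bool(p.uses_anxiolytics) if p.uses_anxiolytics is not None else False
    non_age = (
        c["bmi"] * db + c["bmi_sq"] * db * db
        + c["female"] * (sex == "female")
        + c["hypertension"] * hypertension
        + c["calendar_year"] * (year - eq.year_center)
        + c.get(f"deprivation_q{quintile}", 0.0)
        + c["former_smoker"] * (smoking == "former")
        + c["current_smoker"] * (smoking == "current")
        + c["heavy_drinking"] * bool(heavy)
        + c["depression_or_antidepressants"] * (bool(depressive) or bool(antidep))
        + c["aspirin"] * bool(aspirin)
        + c["stroke_or_tia"] * (bool(stroke) or bool(tia))
        + c["atrial_fibrillation"] * bool(af)
        + c["diabetes"] * bool(diabetes)
        + c.get("anxiety", 0.0) * anxiety
    )
    return ScoreComponents("drs", age_part + non_age, age_part, non_age)


def drs_risk(linear_predictor: float, eq: DrsEquation) -> float:
    """Predicted 5-year dementia risk as a percentage:
    100 * (1 - S^exp(P)) with S the equation's baseline survival."""
    return 100.0 * (1.0 - eq.baseline_survival ** math.exp(linear_predictor))


def drs_score(p: Participant, registry: dict | None = None,
              tables: dict | None = None) -> ScoreComponents:
    """Full DRS evaluation with age-band stitching and absolute risk."""
    if registry is None:
        registry = default_drs_registry(tables)
    age = p.require("age")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eq = drs_select_equation(age, registry)
        comp = drs_linear_predictor(p, eq, tables)
    comp.predicted_risk = drs_risk(comp.total, eq) / 100.0
    return comp


# --------------------------------------------------------------------------
# variants and cohort scoring
# --------------------------------------------------------------------------


def score_participant(model: str, p: Participant, *,
                      extrapolate_age: bool = True,
                      adaptation: str = "rotterdam",
                      drs_registry: dict | None = None,
                      caide_risk_table: dict | None = None,
                      tables: dict | None = None) -> ScoreComponents:
    """Score one participant with one model (full decomposition)."""
    if model == "caide":
        comp = caide_score(p, tables)
        if caide_risk_table:
            comp.predicted_risk = caide_predicted_risk(comp.total, caide_risk_table)
        return comp
    if model == "bdsi":
        return bdsi_score(p, extrapolate_age=extrapolate_age, tables=tables)
    if model == "anu_adri":
        return anu_adri_score(p, adaptation=adaptation, tables=tables)
    if model == "drs":
        return drs_score(p, registry=drs_registry, tables=tables)
    raise ValueError(f"unknown model '{model}'")


def score_variant(model: str, variant: str, p: Participant,
                  **kwargs) -> float:
    """One model variant for one participant: ``full`` is the total score,
    ``age_only`` the age(+sex for ANU-ADRI age grid) component, and
    ``without_age`` the remainder; age_only + without_age = full exactly."""
    return score_participant(model, p, **kwargs).variant(variant)


def score_cohort(cohort: pd.DataFrame, model: str, variant: str = "full",
                 **kwargs) -> np.ndarray:
    """Vectorised cohort scoring; returns one predictor value per row.

    Missing required inputs raise :class:`MissingInputError` (score complete
    or imputed cohorts).
    """
    values = np.empty(len(cohort))
    for i, row in enumerate(cohort.to_dict("records")):
        p = participant_from_row(row)
        values[i] = score_participant(model, p, **kwargs).variant(variant)
    return values


def predicted_risk_cohort(cohort: pd.DataFrame, model: str,
                          **kwargs) -> np.ndarray:
    """Absolute predicted risks (probabilities); NaN where the model has no
    configured risk mapping."""
    values = np.full(len(cohort), np.nan)
    for i, row in enumerate(cohort.to_dict("records")):
        p = participant_from_row(row)
        risk = score_participant(model, p, **kwargs).predicted_risk
        if risk is not None:
            values[i] = risk
    return values
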