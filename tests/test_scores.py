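"""Worked examples and invariants of the four risk scorers."""

import dataclasses
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demrisk import scores
from demrisk.schema import MissingInputError
from tests.conftest import make_participant


class TestCaide:
    def test_all_reference_categories_score_zero(self):
        p = make_participant(age=45, sex="female", education_years=12,
                             sbp=130, bmi=24, total_cholesterol=5.0,
                             active_minutes_met4=60)
        assert scores.caide_score(p).total == 0

    def test_worst_categories_sum_to_fifteen(self):
        p = make_participant(age=60, sex="male", education_years=5,
                             sbp=150, bmi=31, total_cholesterol=7.0,
                             active_minutes_met4=10)
        assert scores.caide_score(p).total == 4 + 1 + 3 + 2 + 2 + 2 + 1 == 15

    def test_age_47_scores_three_age_points(self):
        p = make_participant(age=47)
        assert scores.caide_score(p).age_points == 3

    @pytest.mark.parametrize("sbp,bmi,chol,expected", [
        (140.0, 30.0, 6.5, 0),   # ties go to the lower-point category
        (140.1, 30.1, 6.6, 6),
    ])
    def test_strict_inequalities_at_thresholds(self, sbp, bmi, chol, expected):
        p = make_participant(age=45, sbp=sbp, bmi=bmi, total_cholesterol=chol)
        assert scores.caide_score(p).non_age_points == expected

    def test_missing_required_field_names_it(self):
        p = make_participant(sbp=None)
        with pytest.raises(MissingInputError, match="sbp"):
            scores.caide_score(p)

    def test_met_hours_fallback_when_minutes_unknown(self):
        active = make_participant(active_minutes_met4=None,
                                  physical_activity_met_hours=50.0)
        inactive = make_participant(active_minutes_met4=None,
                                    physical_activity_met_hours=1.0)
        assert scores.caide_score(active).total \
            == scores.caide_score(inactive).total - 1


class TestBdsi:
    def test_anchor_case_scores_zero(self):
        p = make_participant(age=65, education_years=13, bmi=25)
        assert scores.bdsi_score(p).total == 0

    def test_diabetes_and_stroke_at_seventy(self):
        p = make_participant(age=70, education_years=13, bmi=25,
                             diabetes=True, stroke=True)
        assert scores.bdsi_score(p).total == 5 + 3 + 6 == 14

    def test_age_extrapolation_one_point_per_year(self):
        p = make_participant(age=85, education_years=13, bmi=25)
        assert scores.bdsi_score(p, extrapolate_age=True).age_points == 20

    def test_outside_design_range_raises_without_flag(self):
        p = make_participant(age=85, education_years=13, bmi=25)
        with pytest.raises(scores.DesignRangeError):
            scores.bdsi_score(p, extrapolate_age=False)

    def test_non_age_points_bounded(self):
        worst = make_participant(age=70, education_years=5, bmi=17,
                                 diabetes=True, stroke=True,
                                 needs_help_finances_medications=True,
                                 depressive_symptoms=True)
        assert scores.bdsi_score(worst).non_age_points == 42


def anu_reference(**kw):
    base = dict(age=60, sex="male", education_years=5, total_cholesterol=5.0,
                diabetes=False, head_trauma=False, depressive_symptoms=False,
                smoking="never", alcohol_user=False, heavy_drinking=False,
                bmi=22, fish_servings_week="<=0.25",
                physical_activity_met_hours=10.0,
                living_with_partner=True, married=True, lonely=False)
    base.update(kw)
    return make_participant(**base)


class TestAnuAdri:
    def test_reference_man_under_65_scores_zero(self):
        assert scores.anu_adri_score(anu_reference()).total == 0

    def test_protective_items_sum(self):
        p = anu_reference(alcohol_user=True, physical_activity_met_hours=100.0,
                          fish_servings_week="2.1-4.0")
        assert scores.anu_adri_score(p).total == -3 - 3 - 4 == -10

    def test_deleterious_items_sum(self):
        p = anu_reference(smoking="current", diabetes=True,
                          depressive_symptoms=True)
        assert scores.anu_adri_score(p).total == 4 + 3 + 2 == 9

    def test_age_grid_endpoints(self):
        man = anu_reference(age=60)
        woman = anu_reference(age=95, sex="female")
        assert scores.anu_adri_score(man).age_points == 0
        assert scores.anu_adri_score(woman).age_points == 41

    def test_three_domain_social_composite(self):
        isolated = anu_reference(living_with_partner=False, married=False,
                                 lonely=True)
        assert scores.anu_adri_score(isolated).total \
            == scores.anu_adri_score(anu_reference()).total + 6

    def test_original_adaptation_requires_extra_items(self):
        with pytest.raises(MissingInputError):
            scores.anu_adri_score(anu_reference(), adaptation="original")

    def test_original_adaptation_scores_extra_items(self):
        p = anu_reference(social_engagement="high")
        comp = scores.anu_adri_score(p, adaptation="original",
                                     pesticide_exposure=True,
                                     cognitive_activity="high")
        assert comp.total == 2 - 7


def drs_reference(**kw):
    base = dict(age=65.608, bmi=27.501, sex="male", sbp=120.0,
                uses_antihypertensives=False, calendar_year=2003.719,
                smoking="never", heavy_drinking=False,
                depressive_symptoms=False, uses_antidepressants=False,
                uses_aspirin=False, stroke=False, tia=False,
                atrial_fibrillation=False, diabetes=False,
                living_with_partner=True, married=True, lonely=False)
    base.update(kw)
    return make_participant(**base)


@pytest.fixture(scope="module")
def eq():
    return scores.default_drs_registry()["60-79"]


class TestDrs:
    def test_every_term_vanishes_at_reference(self, eq):
        assert scores.drs_linear_predictor(drs_reference(), eq).total \
            == pytest.approx(0.0, abs=1e-12)

    def test_stroke_or_tia_coefficient(self, eq):
        p = drs_reference(stroke=True)
        assert scores.drs_linear_predictor(p, eq).total \
            == pytest.approx(0.577207, abs=1e-12)
        p_tia = drs_reference(tia=True)
        assert scores.drs_linear_predictor(p_tia, eq).total \
            == pytest.approx(0.577207, abs=1e-12)

    def test_calendar_year_coefficient(self, eq):
        p = drs_reference(calendar_year=2004.719)
        assert scores.drs_linear_predictor(p, eq).total \
            == pytest.approx(0.04477, abs=1e-12)

    def test_risk_at_reference_is_0_31_percent(self, eq):
        assert scores.drs_risk(0.0, eq) == pytest.approx(0.31, abs=1e-9)

    def test_risk_vanishes_for_very_low_predictor(self, eq):
        assert scores.drs_risk(-50.0, eq) < 1e-12

    def test_risk_strictly_increasing_in_predictor(self, eq):
        grid = np.linspace(-5, 5, 41)
        risks = [scores.drs_risk(p, eq) for p in grid]
        assert np.all(np.diff(risks) > 0)

    def test_equation_selection_by_age(self, eq):
        old_eq = dataclasses.replace(eq, age_band="80-95")
        registry = {"60-79": eq, "80-95": old_eq}
        assert scores.drs_select_equation(70, registry) is eq
        assert scores.drs_select_equation(85, registry) is old_eq
        assert scores.drs_select_equation(79.5, registry) is eq

    def test_missing_old_equation_falls_back_with_warning(self, eq):
        with pytest.warns(UserWarning, match="80-95"):
            got = scores.drs_select_equation(85, {"60-79": eq})
        assert got is eq

    def test_age_below_sixty_warns_but_computes(self, eq):
        with pytest.warns(UserWarning, match="below"):
            comp = scores.drs_linear_predictor(drs_reference(age=57.0), eq)
        assert math.isfinite(comp.total)


class TestDeprivationQuintile:
    @pytest.mark.parametrize("lwp,married,lonely,expected", [
        (True, True, False, 1),
        (False, True, False, 2),
        (False, False, False, 4),
        (False, False, True, 5),
    ])
    def test_default_mapping(self, lwp, married, lonely, expected):
        assert scores.deprivation_quintile(lwp, married, lonely) == expected

    def test_missing_input_raises(self):
        with pytest.raises(MissingInputError):
            scores.deprivation_quintile(None, True, False)


# ---------------------------------------------------------------------------
# invariants across models
# ---------------------------------------------------------------------------

participant_strategy = st.builds(
    make_participant,
    age=st.floats(55, 95),
    sex=st.sampled_from(["female", "male"]),
    education_years=st.floats(0, 20),
    sbp=st.floats(90, 220),
    bmi=st.floats(16, 45),
    total_cholesterol=st.floats(3, 9),
    physical_activity_met_hours=st.floats(0, 200),
    active_minutes_met4=st.floats(0, 600),
    diabetes=st.booleans(), stroke=st.booleans(), tia=st.booleans(),
    atrial_fibrillation=st.booleans(), head_trauma=st.booleans(),
    depressive_symptoms=st.booleans(),
    needs_help_finances_medications=st.booleans(),
    smoking=st.sampled_from(["never", "former", "current"]),
    alcohol_user=st.booleans(), heavy_drinking=st.booleans(),
    living_with_partner=st.booleans(), married=st.booleans(),
    lonely=st.booleans(),
    fish_servings_week=st.sampled_from(["<=0.25", "0.26-2.0", "2.1-4.0",
                                        ">=4.1"]),
    uses_antihypertensives=st.booleans(), uses_aspirin=st.booleans(),
    uses_antidepressants=st.booleans(), uses_anxiolytics=st.booleans(),
    calendar_year=st.floats(1997, 2001),
)


@settings(max_examples=100, deadline=None)
@given(p=participant_strategy, model=st.sampled_from(scores.MODELS))
def test_age_and_non_age_components_decompose_total(p, model):
    """age_only + without_age = full, exactly for point scores and to 1e-12
    for the DRS linear predictor."""
    comp = scores.score_participant(model, p)
    assert comp.age_points + comp.non_age_points \
        == pytest.approx(comp.total, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(p=participant_strategy)
def test_deleterious_items_never_decrease_scores(p):
    """Switching a harmful item on never lowers any model's total."""
    worse = dataclasses.replace(p, diabetes=True, stroke=True,
                                depressive_symptoms=True)
    for model in scores.MODELS:
        assert scores.score_participant(model, worse).total \
            >= scores.score_participant(model, p).total


@settings(max_examples=50, deadline=None)
@given(p=participant_strategy)
def test_protective_items_never_increase_anu_adri(p):
    protective = dataclasses.replace(
        p, alcohol_user=True, heavy_drinking=False,
        physical_activity_met_hours=150.0, fish_servings_week=">=4.1",
    )
    baseline = dataclasses.replace(
        p, alcohol_user=False, physical_activity_met_hours=0.0,
        fish_servings_week="<=0.25",
    )
    assert scores.anu_adri_score(protective).total \
        <= scores.anu_adri_score(baseline).total


@settings(max_examples=60, deadline=None)
@given(p=participant_strategy)
def test_score_bounds(p):
    assert 0 <= scores.caide_score(p).total <= 15
    assert 0 <= scores.bdsi_score(p, extrapolate_age=True).non_age_points <= 42
    risk = scores.drs_score(p).predicted_risk
    assert 0 < risk < 1


def test_cohort_scoring_is_row_independent(small_cohort):
    sub = small_cohort.head(40)
    values = scores.score_cohort(sub, "bdsi", "full")
    perm = np.random.default_rng(0).permutation(len(sub))
    shuffled = scores.score_cohort(sub.iloc[perm].reset_index(drop=True),
                                   "bdsi", "full")
    assert np.allclose(values[perm], shuffled)


def test_variant_selection_matches_components(reference_participant):
    comp = scores.score_participant("bdsi", reference_participant)
    assert scores.score_variant("bdsi", "full", reference_participant) \
        == comp.total
    assert scores.score_variant("bdsi", "age_only", reference_participant) \
        == comp.age_points
    assert scores.score_variant("bdsi", "without_age", reference_participant) \
        == comp.non_age_points
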