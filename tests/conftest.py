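import dataclasses

import numpy as np
import pytest

from demrisk import simulate
from demrisk.schema import Participant


def make_participant(**kw) -> Participant:
    """A fully specified reference participant; override fields as needed."""
    base = dict(
        id="p1", wave="original", age=70.0, sex="female",
        education_years=12.0, sbp=130.0, bmi=24.0, total_cholesterol=5.0,
        hdl_cholesterol=1.4, physical_activity_met_hours=60.0,
        active_minutes_met4=120.0, diabetes=False, stroke=False, tia=False,
        atrial_fibrillation=False, head_trauma=False,
        depressive_symptoms=False, needs_help_finances_medications=False,
        smoking="never", alcohol_user=False, heavy_drinking=False,
        social_engagement="high", living_with_partner=True, married=True,
        lonely=False, fish_servings_week="<=0.25",
        uses_antihypertensives=False, uses_anxiolytics=False,
        uses_aspirin=False, uses_antidepressants=False, uses_nsaids=False,
        calendar_year=2000.0,
    )
    base.update(kw)
    return Participant(**base)


def scaled_config(n_total: int, **overrides) -> simulate.GeneratorConfig:
    """Default generator config scaled to a smaller cohort, keeping the
    two-wave mix proportional."""
    cfg = simulate.default_config(**overrides)
    frac = n_total / cfg.n_total
    cfg.n_original = round(cfg.n_original * frac)
    cfg.n_extended = n_total - cfg.n_original
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    """A complete (no-missingness) cohort of ~1200 for metric tests."""
    return simulate.generate_cohort(scaled_config(1200), seed=42,
                                    missingness=False)


@pytest.fixture(scope="session")
def small_cohort_missing():
    """Same scale, with the default missingness pattern injected."""
    return simulate.generate_cohort(scaled_config(1200), seed=42,
                                    missingness=True)


@pytest.fixture()
def reference_participant():
    return make_participant()
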