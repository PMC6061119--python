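"""Discrimination/calibration machinery against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from demrisk import metrics


def concordance_oracle(pred, time, event):
    """Exhaustive O(n^2) pair enumeration, independent of the implementation.

    Comparable pair: the member with the strictly shorter time had an event.
    Concordant: that member has the higher predictor; predictor ties 0.5.
    """
    num = 0.0
    comparable = 0
    n = len(pred)
    for i in range(n):
        for j in range(n):
            if i == j or time[i] >= time[j] or not event[i]:
                continue
            comparable += 1
            if pred[i] > pred[j]:
                num += 1.0
            elif pred[i] == pred[j]:
                num += 0.5
    if comparable == 0:
        return None, 0
    return num / comparable, comparable


def random_censored_cohort(rng, n):
    pred = rng.choice(np.arange(20.0), size=n)  # deliberate predictor ties
    time = np.round(rng.exponential(5, size=n), 1) + 0.1  # some time ties
    event = rng.random(n) < 0.5
    return pred, time, event


class TestHarrellC:
    def test_single_concordant_pair(self):
        res = metrics.harrell_c([2, 1], [5, 10], [True, True], n_bootstrap=0)
        assert res.c == 1.0 and res.n_comparable_pairs == 1

    def test_shorter_censored_time_not_comparable(self):
        with pytest.raises(metrics.NoComparablePairsError):
            metrics.harrell_c([2, 1], [5, 10], [False, True], n_bootstrap=0)

    def test_no_events_is_error(self):
        with pytest.raises(metrics.NoComparablePairsError):
            metrics.harrell_c([1, 2, 3], [1, 2, 3], [False] * 3)

    def test_constant_predictor_degenerate_half(self):
        res = metrics.harrell_c([3, 3, 3], [1, 2, 3], [True, True, False])
        assert res.degenerate and res.c == 0.5

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 60))
    def test_matches_exhaustive_pair_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        pred, time, event = random_censored_cohort(rng, n)
        expected, comparable = concordance_oracle(pred, time, event)
        if expected is None or np.all(pred == pred[0]):
            return
        res = metrics.harrell_c(pred, time, event, n_bootstrap=0)
        assert res.c == pytest.approx(expected, abs=1e-12)
        assert res.n_comparable_pairs == comparable

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        pred, time, event = random_censored_cohort(rng, 80)
        a = metrics.harrell_c(pred, time, event, n_bootstrap=0).c
        b = metrics.harrell_c(np.exp(0.3 * pred), time, event, n_bootstrap=0).c
        assert a == b

    def test_reversal_identity_without_predictor_ties(self):
        rng = np.random.default_rng(4)
        n = 60
        pred = rng.permutation(np.arange(n, dtype=float))  # no ties
        time = np.round(rng.exponential(5, size=n), 1) + 0.1
        event = rng.random(n) < 0.6
        c = metrics.harrell_c(pred, time, event, n_bootstrap=0).c
        c_neg = metrics.harrell_c(-pred, time, event, n_bootstrap=0).c
        assert c_neg == pytest.approx(1 - c, abs=1e-12)

    def test_perfect_predictor_no_censoring(self):
        rng = np.random.default_rng(5)
        time = rng.exponential(5, 100) + 0.01
        res = metrics.harrell_c(-time, time, np.ones(100, bool), n_bootstrap=0)
        assert res.c == 1.0

    def test_independent_predictor_near_half(self):
        rng = np.random.default_rng(6)
        n = 2000
        time = rng.exponential(5, n) + 0.01
        pred = rng.standard_normal(n)
        res = metrics.harrell_c(pred, time, np.ones(n, bool), n_bootstrap=0)
        se = 1.0 / np.sqrt(n)  # conservative Monte-Carlo scale
        assert abs(res.c - 0.5) < 3 * se

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        rng = np.random.default_rng(7)
        pred, time, event = random_censored_cohort(rng, 100)
        a = metrics.harrell_c(pred, time, event, n_bootstrap=100, seed=1)
        b = metrics.harrell_c(pred, time, event, n_bootstrap=100, seed=1)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.c <= a.ci_high


class TestTruncation:
    def test_event_beyond_horizon_becomes_censored_at_horizon(self):
        t, e = metrics.truncate_at_horizon([12.0], [True], 10.0)
        assert t[0] == 10.0 and not e[0]

    def test_event_within_horizon_unchanged(self):
        t, e = metrics.truncate_at_horizon([8.0], [True], 10.0)
        assert t[0] == 8.0 and e[0]

    def test_events_nest_across_horizons(self, small_cohort):
        time = small_cohort["time"].astype(float).to_numpy()
        event = (small_cohort["event"] == "dementia").to_numpy()
        counts = []
        for h in (2, 5, 10, 15):
            _, e = metrics.truncate_at_horizon(time, event, h)
            counts.append(e.sum())
        assert counts == sorted(counts)
        _, e5 = metrics.truncate_at_horizon(time, event, 5)
        _, e10 = metrics.truncate_at_horizon(time, event, 10)
        assert not np.any(e5 & ~e10)  # strict subset relation


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        s, _ = metrics.kaplan_meier([1, 2, 3], [False] * 3, 3.0)
        assert s == 1.0

    def test_hand_computed_product_limit(self):
        # risk sets: t=1 (3 at risk, 1 event), t=3 (1 at risk, 1 event)
        s, flag = metrics.kaplan_meier([1, 2, 3], [True, False, True], 3.0)
        assert s == pytest.approx((1 - 1 / 3) * (1 - 1 / 1), abs=1e-12)
        assert not flag

    def test_nonincreasing_in_time(self, small_cohort):
        time = small_cohort["time"].astype(float).to_numpy()
        event = (small_cohort["event"] == "dementia").to_numpy()
        values = [metrics.kaplan_meier(time, event, t)[0]
                  for t in (1, 5, 10, 15)]
        assert values == sorted(values, reverse=True)

    def test_extrapolation_flagged(self):
        s, flag = metrics.kaplan_meier([1, 2], [False, False], 10.0)
        assert flag and s == 1.0


class TestCalibration:
    @staticmethod
    def simulated_records(n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        pred = expit(rng.normal(-2.0, 1.0, n))
        y = rng.random(n) < pred
        time = np.where(y, 5.0, 11.0)  # events inside, censoring beyond horizon
        return pred, time, y

    def test_self_consistent_predictions_recover_identity(self):
        """Outcomes drawn from the stated risks: slope ~1, intercept ~0."""
        pred, time, y = self.simulated_records()
        res = metrics.calibration_intercept_slope(pred, time, y, 10.0)
        assert res.slope == pytest.approx(1.0, abs=0.05)
        assert res.intercept == pytest.approx(0.0, abs=0.05)
        assert res.n_used == len(pred)

    def test_doubled_odds_shift_intercept_not_slope(self):
        pred, time, y = self.simulated_records(seed=1)
        inflated = expit(logit(pred) + np.log(2))
        base = metrics.calibration_intercept_slope(pred, time, y, 10.0)
        shifted = metrics.calibration_intercept_slope(inflated, time, y, 10.0)
        assert shifted.intercept - base.intercept \
            == pytest.approx(-np.log(2), abs=1e-6)
        assert shifted.slope == pytest.approx(base.slope, abs=1e-6)

    def test_censored_before_horizon_excluded(self):
        pred = np.array([0.2, 0.2, 0.2, 0.2])
        time = np.array([3.0, 12.0, 5.0, 11.0])
        event = np.array([True, False, False, False])
        # the t=5 censored-dementia-free subject carries no 10-y outcome
        with pytest.raises(metrics.DegenerateInputError):
            # constant predictions -> slope undefined, but exclusion first
            metrics.calibration_intercept_slope(pred, time, event, 10.0)
        y, kept = metrics._binary_outcome_at_horizon(time, event, 10.0)
        assert kept.tolist() == [True, True, False, True]

    def test_all_identical_outcomes_non_identifiable(self):
        pred = np.array([0.1, 0.5, 0.9])
        with pytest.raises(metrics.DegenerateInputError):
            metrics.calibration_intercept_slope(
                pred, [11, 11, 11], [False] * 3, 10.0
            )

    @pytest.mark.filterwarnings(
        "ignore::statsmodels.tools.sm_exceptions.PerfectSeparationWarning")
    def test_near_perfect_predictions_flag_steep_slope(self):
        rng = np.random.default_rng(2)
        n = 400
        y = rng.random(n) < 0.5
        pred = np.where(y, 1 - 1e-4, 1e-4)
        time = np.where(y, 5.0, 11.0)
        res = metrics.calibration_intercept_slope(pred, time, y, 10.0)
        assert res.slope > 1.0

    def test_decile_bins_cover_all_kept_subjects(self):
        pred, time, y = self.simulated_records(n=5000, seed=3)
        res = metrics.calibration_intercept_slope(pred, time, y, 10.0)
        assert sum(b[4] for b in res.bins) == res.n_used
        means = [b[0] for b in res.bins]
        assert means == sorted(means)


class TestRecalibration:
    def test_logistic_mean_matching_identity(self):
        rng = np.random.default_rng(0)
        n = 4000
        pred = expit(rng.normal(-2.5, 0.8, n))
        y = rng.random(n) < np.clip(pred * 1.8, 0, 1)
        time = np.where(y, 4.0, 12.0)
        updated, delta = metrics.recalibrate_logistic(pred, time, y, 10.0)
        assert updated.mean() == pytest.approx(y.mean(), abs=1e-10)

    def test_doubled_small_risks_shift_by_log_two(self):
        rng = np.random.default_rng(1)
        n = 200_000
        pred = np.full(n, 0.01)
        y = rng.random(n) < 0.02
        time = np.where(y, 4.0, 12.0)
        _, delta = metrics.recalibrate_logistic(pred, time, y, 10.0)
        assert delta == pytest.approx(np.log(2), abs=0.05)

    def test_already_calibrated_delta_near_zero(self):
        rng = np.random.default_rng(2)
        n = 50_000
        pred = np.full(n, 0.1)
        y = rng.random(n) < 0.1
        time = np.where(y, 4.0, 12.0)
        _, delta = metrics.recalibrate_logistic(pred, time, y, 10.0)
        assert abs(delta) < 0.1

    def test_cox_constant_predictor_returns_km_risk(self):
        rng = np.random.default_rng(3)
        n = 500
        time = rng.exponential(8, n) + 0.01
        event = rng.random(n) < 0.6
        lp = np.zeros(n)
        risks, s_base, _ = metrics.recalibrate_cox(lp, time, event, 5.0)
        t5, e5 = metrics.truncate_at_horizon(time, event, 5.0)
        km, _ = metrics.kaplan_meier(t5, e5, 5.0)
        assert np.allclose(risks, 1 - km)
        assert s_base == pytest.approx(km, abs=1e-12)

    def test_cox_risks_increase_with_linear_predictor(self):
        rng = np.random.default_rng(4)
        n = 300
        lp = np.sort(rng.normal(0, 1, n))
        time = rng.exponential(8, n) + 0.01
        event = rng.random(n) < 0.5
        risks, _, _ = metrics.recalibrate_cox(lp, time, event, 5.0)
        assert np.all(np.diff(risks) > 0)

    def test_cox_recalibration_on_proportional_hazards_data(self):
        """Data generated under proportional hazards with known LPs:
        recalibrated risks show calibration slope ~1 at n=5000."""
        rng = np.random.default_rng(5)
        n = 5000
        lp = rng.normal(0, 0.8, n)
        base_rate = 0.02
        time = rng.exponential(1 / (base_rate * np.exp(lp)))
        censor = np.full(n, 14.0)
        obs = np.minimum(time, censor)
        event = time <= censor
        risks, _, _ = metrics.recalibrate_cox(lp, obs, event, 10.0)
        res = metrics.calibration_intercept_slope(
            np.clip(risks, 1e-12, 1 - 1e-12), obs, event, 10.0
        )
        assert 0.9 <= res.slope <= 1.1


class TestIncidence:
    def test_hand_arithmetic(self):
        assert metrics.incidence_rate([50.0, 50.0], [True, True]) == 20.0

    def test_no_events_zero(self):
        assert metrics.incidence_rate([10.0, 5.0], [False, False]) == 0.0

    def test_printed_cohort_scale(self):
        # 867 events over 75,581 person-years ~ 11.5 per 1000 PY
        time = np.full(6667, 75_581 / 6667)
        event = np.zeros(6667, bool)
        event[:867] = True
        assert metrics.incidence_rate(time, event) == pytest.approx(11.47, abs=0.01)
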