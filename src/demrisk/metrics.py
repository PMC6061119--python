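"""Discrimination, calibration and recalibration for censored predictions.

The concordance statistic here is Harrell's C for right-censored data: over
all *comparable* pairs -- the member with the shorter follow-up time had the
event, and the times differ -- the fraction in which that member also has the
higher predictor, ties in the predictor credited 1/2.  Confidence intervals
come from a seedable nonparametric bootstrap (percentile, 500 replicates by
default); the pair counting itself is exact, not approximated.

Calibration of absolute risk predictions at a horizon uses the standard
logistic framework: the calibration slope is the coefficient of
logit(predicted risk) in a logistic regression of the binary
event-by-horizon outcome, and the calibration intercept
(calibration-in-the-large) is the intercept of the same regression with the
slope fixed at 1 (logit(predicted) as offset).  Participants censored
dementia-free before the horizon are excluded from the binary outcome; a
Kaplan-Meier-based per-decile observed risk is available as a
censoring-robust alternative for the plot data.

Two recalibration procedures are provided: an intercept update for logistic
models (shift predictions on the logit scale until the mean matches the
observed event proportion) and the Cox-type update (replace the baseline
survival at the horizon by the validation Kaplan-Meier estimate and centre
the linear predictor at the validation mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from lifelines import KaplanMeierFitter
from numba import njit
from scipy import optimize
from scipy.special import expit, logit
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint


class NoComparablePairsError(ValueError):
    """No events, or no comparable pairs: concordance is undefined."""


class DegenerateInputError(ValueError):
    """Inputs carry no usable variation (e.g. all outcomes identical)."""


@dataclass
class ConcordanceResult:
    """Harrell's C with its bootstrap confidence interval."""

    c: float
    n_comparable_pairs: int
    se: float
    ci_low: float
    ci_high: float
    ci_method: str
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate and not (self.ci_low <= self.c <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")


@dataclass
class CalibrationResult:
    """Calibration intercept/slope plus the decile plot data.

    ``bins`` rows are (mean predicted risk, observed risk, ci_low, ci_high, n).
    """

    intercept: float
    slope: float
    bins: list = field(default_factory=list)
    n_used: int = 0
    separation_flag: bool = False


# --------------------------------------------------------------------------
# horizon truncation
# --------------------------------------------------------------------------


def truncate_at_horizon(time, event, horizon: float):
    """Recode follow-up at a prediction horizon: times are capped at the
    horizon and events beyond it count as censored at the horizon."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    new_time = np.minimum(time, horizon)
    new_event = event & (time <= horizon)
    return new_time, new_event


# --------------------------------------------------------------------------
# Harrell's C
# --------------------------------------------------------------------------


@njit(cache=True)
def _concordance_counts(pred, time, event):
    """Exact pair counting: (concordant, tied-predictor, comparable)."""
    n = len(pred)
    concordant = 0.0
    tied = 0.0
    comparable = 0.0
    for i in range(n):
        if not event[i]:
            continue
        ti = time[i]
        pi = pred[i]
        for j in range(n):
            if time[j] > ti:
                comparable += 1.0
                if pred[j] < pi:
                    concordant += 1.0
                elif pred[j] == pi:
                    tied += 1.0
    return concordant, tied, comparable


def _c_from_counts(pred, time, event) -> tuple[float, int]:
    conc, tied, comp = _concordance_counts(
        np.ascontiguousarray(pred, dtype=np.float64),
        np.ascontiguousarray(time, dtype=np.float64),
        np.ascontiguousarray(event, dtype=np.bool_),
    )
    if comp == 0:
        raise NoComparablePairsError("no comparable pairs")
    return (conc + 0.5 * tied) / comp, int(comp)


def harrell_c(pred, time, event, n_bootstrap: int = 500,
              seed: int = 0) -> ConcordanceResult:
    """Harrell's concordance for censored data with a bootstrap CI.

    ``n_bootstrap=0`` skips the interval (SE and CI reported as NaN).  A
    constant predictor yields a degenerate result flagged as such with
    C = 0.5.  Raises :class:`NoComparablePairsError` when no events or no
    comparable pairs exist.
    """
    pred = np.asarray(pred, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(pred) < 2:
        raise NoComparablePairsError("need at least two records")
    if not event.any():
        raise NoComparablePairsError("no events observed")
    if not np.isfinite(pred).all():
        raise ValueError("predictor values must be finite")

    if np.all(pred == pred[0]):
        return ConcordanceResult(
            c=0.5, n_comparable_pairs=0, se=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"),
            ci_method="degenerate", degenerate=True,
        )

    c, comp = _c_from_counts(pred, time, event)
    if n_bootstrap <= 0:
        return ConcordanceResult(c, comp, float("nan"), c, c, "none")

    rng = np.random.default_rng(seed)
    n = len(pred)
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            reps[b], _ = _c_from_counts(pred[idx], time[idx], event[idx])
        except NoComparablePairsError:
            reps[b] = np.nan
    reps = reps[np.isfinite(reps)]
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return ConcordanceResult(
        c=c, n_comparable_pairs=comp, se=float(reps.std(ddof=1)),
        ci_low=float(min(lo, c)), ci_high=float(max(hi, c)),
        ci_method=f"bootstrap-percentile-{n_bootstrap}",
    )


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------


def kaplan_meier(time, event, t: float) -> tuple[float, bool]:
    """Product-limit event-free probability at ``t``.

    Returns ``(survival, extrapolated)``; the flag marks a query beyond the
    last observed time, where the last estimate is carried forward.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    km = KaplanMeierFitter()
    km.fit(time, event_observed=event)
    s = float(km.survival_function_at_times(t).iloc[0])
    return s, bool(t > time.max())


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------


def _binary_outcome_at_horizon(time, event, horizon):
    """Event-by-horizon indicator and the kept-subject mask.

    Subjects censored dementia-free before the horizon carry no usable binary
    outcome and are excluded.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    event_by_h = event & (time <= horizon)
    kept = event_by_h | (time >= horizon)
    return event_by_h, kept


def calibration_intercept_slope(predicted_risk, time, event, horizon: float,
                                n_bins: int = 10,
                                km_bins: bool = False) -> CalibrationResult:
    """Calibration intercept and slope of predictions at a horizon.

    ``km_bins=True`` computes the per-decile observed risks by Kaplan-Meier
    (censoring-robust) instead of raw proportions among the kept subjects;
    the intercept/slope fits always use the binary-outcome construction.
    """
    p = np.asarray(predicted_risk, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted risks must lie strictly in (0, 1)")
    y_all, kept = _binary_outcome_at_horizon(time, event, horizon)
    y = y_all[kept].astype(float)
    x = logit(p[kept])
    if len(y) == 0 or y.min() == y.max():
        raise DegenerateInputError("all outcomes identical; fit is non-identifiable")
    if np.all(x == x[0]):
        raise DegenerateInputError("constant predictions; slope undefined")

    slope_fit = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    slope = float(slope_fit.params[1])
    offset_fit = sm.GLM(y, np.ones((len(y), 1)), offset=x,
                        family=sm.families.Binomial()).fit()
    intercept = float(offset_fit.params[0])

    # decile plot data
    order = np.argsort(p[kept], kind="stable")
    edges = np.array_split(order, n_bins)
    time_k = np.asarray(time, dtype=float)[kept]
    event_k = np.asarray(event, dtype=bool)[kept]
    bins = []
    for idx in edges:
        if len(idx) == 0:
            continue
        mean_pred = float(p[kept][idx].mean())
        if km_bins:
            s, _ = kaplan_meier(time_k[idx], event_k[idx], horizon)
            obs = 1.0 - s
            lo, hi = float("nan"), float("nan")
        else:
            k = int(y[idx].sum())
            obs = k / len(idx)
            lo, hi = proportion_confint(k, len(idx), method="wilson")
        bins.append((mean_pred, float(obs), float(lo), float(hi), int(len(idx))))

    return CalibrationResult(
        intercept=intercept, slope=slope, bins=bins, n_used=int(kept.sum()),
        separation_flag=bool(slope > 1.0 and abs(intercept) < 0.1),
    )


# --------------------------------------------------------------------------
# recalibration
# --------------------------------------------------------------------------


def recalibrate_logistic(predicted_risk, time, event,
                         horizon: float) -> tuple[np.ndarray, float]:
    """Intercept update for a logistic model.

    Finds the logit shift ``delta`` such that the mean updated prediction
    equals the observed event proportion by the horizon (among subjects with
    a defined binary outcome), and returns ``(updated predictions, delta)``.
    """
    p = np.asarray(predicted_risk, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted risks must lie strictly in (0, 1)")
    y, kept = _binary_outcome_at_horizon(time, event, horizon)
    observed = y[kept].mean() if kept.any() else 0.0
    if observed == 0:
        raise DegenerateInputError("no events by the horizon; cannot recalibrate")
    lp = logit(p)

    def gap(delta):
        return expit(lp[kept] + delta).mean() - observed

    delta = optimize.brentq(gap, -30, 30, xtol=1e-13)
    return expit(lp + delta), float(delta)


def recalibrate_cox(linear_predictor, time, event,
                    horizon: float) -> tuple[np.ndarray, float, float]:
    """Cox-type recalibration: updated baseline survival and centering.

    Estimates the horizon survival S(h) by Kaplan-Meier on the validation
    records and returns ``(risk_i, S(h), mean LP)`` with
    ``risk_i = 1 - S(h)^exp(LP_i - mean LP)``.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.isfinite(lp).all():
        raise ValueError("linear predictors must be finite")
    t_h, e_h = truncate_at_horizon(time, event, horizon)
    s_base, _ = kaplan_meier(t_h, e_h, horizon)
    if s_base <= 0:
        raise DegenerateInputError("baseline survival reached 0 at the horizon")
    risks = 1.0 - s_base ** np.exp(lp - lp.mean())
    return risks, float(s_base), float(lp.mean())


# --------------------------------------------------------------------------
# incidence
# --------------------------------------------------------------------------


def incidence_rate(time, event) -> float:
    """Crude incidence: 1000 x events / total person-years."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(time) == 0:
        raise ValueError("empty cohort")
    total = time.sum()
    if total <= 0:
        raise ValueError("zero total follow-up time")
    return 1000.0 * event.sum() / total
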