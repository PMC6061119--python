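"""Multiple imputation by chained equations, and Rubin's pooling rules.

Missing covariates are imputed with a fully conditional specification: each
incomplete variable is regressed on all other covariates plus the event
indicator and the Nelson-Aalen cumulative hazard of the follow-up time (the
standard survival-outcome transform), cycling until stable.  Per-variable
methods: predictive mean matching for continuous variables (Bayesian
coefficient draw, k nearest predicted donors), a logistic draw for binaries,
and a multinomial-logistic draw for categoricals.  Wave-structured,
fully-missing-in-one-wave variables are imputed from the wave in which they
were observed.

The imputation never alters observed values or any outcome field, and the m
completed cohorts are deterministic given the seed.  Coefficient posteriors
are drawn only for the continuous models; the binary/categorical draws use
the maximum-likelihood fit, a mild understatement of between-imputation
variance documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import NelsonAalenFitter
from sklearn.linear_model import LogisticRegression

from . import schema

OUTCOME_COLUMNS = ("time", "event", "death", "ad_subtype")
NEVER_IMPUTED = ("id", "wave", "calendar_year") + OUTCOME_COLUMNS

PMM_DONORS = 5


class ImputationError(ValueError):
    pass


@dataclass
class ImputationSet:
    """m completed cohorts plus the provenance needed to rerun them."""

    m: int
    seed: int
    cohorts: list = field(default_factory=list)
    methods: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.cohorts)


def _is_na(col: pd.Series) -> np.ndarray:
    return col.isna().to_numpy() | col.apply(lambda v: v is None).to_numpy()


def _variable_kind(name: str) -> str:
    if name in schema.BOOLEAN_COLUMNS:
        return "logistic"
    if name in schema.CATEGORY_COLUMNS:
        return "categorical"
    return "pmm"


def _design_matrix(df: pd.DataFrame, exclude: str, cumhaz: np.ndarray) -> np.ndarray:
    """Numeric design matrix from all covariates except ``exclude``, plus the
    event indicator and cumulative-hazard transform of follow-up time."""
    cols = []
    for name in schema.COVARIATE_COLUMNS:
        if name in ("wave",) or name == exclude:
            continue
        col = df[name]
        if name in schema.BOOLEAN_COLUMNS:
            cols.append(col.astype(bool).astype(float).to_numpy())
        elif name in schema.CATEGORY_COLUMNS:
            levels = schema.CATEGORY_COLUMNS[name]
            for lv in levels[1:]:
                cols.append((col == lv).astype(float).to_numpy())
        else:
            cols.append(col.astype(float).to_numpy())
    cols.append((df["event"] == "dementia").astype(float).to_numpy())
    cols.append(cumhaz)
    X = np.column_stack(cols)
    # guard against degenerate columns
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _draw_pmm(y_obs, X_obs, X_mis, rng) -> np.ndarray:
    """Predictive mean matching with a Bayesian linear-model draw."""
    n, p = X_obs.shape
    X1 = np.column_stack([np.ones(n), X_obs])
    Xm1 = np.column_stack([np.ones(len(X_mis)), X_mis])
    # ridge-stabilised normal equations
    xtx = X1.T @ X1 + 1e-6 * np.eye(p + 1)
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X1.T @ y_obs)
    resid = y_obs - X1 @ beta
    dof = max(n - p - 1, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    beta_star = rng.multivariate_normal(beta, sigma2 * xtx_inv, method="cholesky")
    pred_obs = X1 @ beta
    pred_mis = Xm1 @ beta_star
    # k nearest observed donors per missing case
    order = np.argsort(pred_obs)
    pos = np.searchsorted(pred_obs[order], pred_mis)
    out = np.empty(len(pred_mis))
    k = min(PMM_DONORS, n)
    for i, c in enumerate(pos):
        lo = int(np.clip(c - k // 2, 0, n - k))
        donors = order[lo:lo + k]
        out[i] = y_obs[rng.choice(donors)]
    return out


def _draw_logistic(y_obs, X_obs, X_mis, rng) -> np.ndarray:
    y = np.asarray(y_obs, dtype=float)
    if y.min() == y.max():
        return np.full(len(X_mis), bool(y[0]))
    model = LogisticRegression(max_iter=200)
    model.fit(X_obs, y)
    p = model.predict_proba(X_mis)[:, 1]
    return rng.random(len(X_mis)) < p


def _draw_categorical(y_obs, X_obs, X_mis, levels, rng) -> np.ndarray:
    observed_levels = pd.unique(y_obs)
    if len(observed_levels) == 1:
        return np.full(len(X_mis), observed_levels[0], dtype=object)
    model = LogisticRegression(max_iter=200)
    model.fit(X_obs, y_obs)
    prob = model.predict_proba(X_mis)
    u = rng.random(len(X_mis))[:, None]
    idx = (prob.cumsum(axis=1) < u).sum(axis=1)
    return np.asarray(model.classes_, dtype=object)[np.clip(idx, 0, prob.shape[1] - 1)]


def _cumulative_hazard_transform(df: pd.DataFrame) -> np.ndarray:
    time = df["time"].astype(float).to_numpy()
    event = (df["event"] == "dementia").to_numpy()
    naf = NelsonAalenFitter()
    naf.fit(time, event_observed=event)
    return naf.cumulative_hazard_at_times(time).to_numpy()


def impute(cohort: pd.DataFrame, m: int = 5, seed: int = 0,
           n_cycles: int = 10) -> ImputationSet:
    """Chained-equations multiple imputation of missing covariates.

    Returns ``m`` completed cohorts, deterministic given ``seed``.  Raises
    :class:`ImputationError` for a variable that is 100% missing in the whole
    cohort (no observed donors anywhere).
    """
    df = cohort.reset_index(drop=True)
    for col in OUTCOME_COLUMNS[:2]:
        if _is_na(df[col]).any():
            raise ImputationError(f"outcome field '{col}' may not be missing")

    na_masks = {}
    for name in schema.COVARIATE_COLUMNS:
        if name in NEVER_IMPUTED:
            continue
        mask = _is_na(df[name])
        if mask.all():
            raise ImputationError(
                f"'{name}' is missing for every participant; cannot fit an "
                "imputation model"
            )
        if mask.any():
            mask_required = name in ("age", "sex")
            if mask_required:
                raise ImputationError(f"required field '{name}' has missing values")
            na_masks[name] = mask

    methods = {name: _variable_kind(name) for name in na_masks}
    result = ImputationSet(m=m, seed=seed, methods=methods)
    if not na_masks:
        result.cohorts = [df.copy() for _ in range(m)]
        return result

    cumhaz = _cumulative_hazard_transform(df)
    order = sorted(na_masks, key=lambda v: na_masks[v].sum())

    for imp in range(m):
        rng = np.random.default_rng([seed, imp])
        work = df.copy()
        # initialise by random draws from the observed margins
        for name, mask in na_masks.items():
            observed = work.loc[~mask, name].to_numpy()
            fill = rng.choice(observed, size=int(mask.sum()), replace=True)
            col = work[name].copy()
            col[mask] = fill
            work[name] = col

        for _ in range(n_cycles):
            for name in order:
                mask = na_masks[name]
                X = _design_matrix(work, exclude=name, cumhaz=cumhaz)
                X_obs, X_mis = X[~mask], X[mask]
                kind = methods[name]
                if kind == "pmm":
                    y_obs = df.loc[~mask, name].astype(float).to_numpy()
                    drawn = _draw_pmm(y_obs, X_obs, X_mis, rng)
                elif kind == "logistic":
                    y_obs = df.loc[~mask, name].astype(bool).to_numpy()
                    drawn = _draw_logistic(y_obs, X_obs, X_mis, rng)
                else:
                    y_obs = df.loc[~mask, name].astype(str).to_numpy()
                    drawn = _draw_categorical(
                        y_obs, X_obs, X_mis, schema.CATEGORY_COLUMNS[name], rng
                    )
                col = work[name].copy()
                col[mask] = drawn
                work[name] = col
        result.cohorts.append(work)
    return result


def pool_rubin(estimates, ses) -> tuple[float, float, float]:
    """Rubin's rules: pooled estimate, pooled SE, total variance.

    Total variance = mean within-imputation variance + (1 + 1/m) times the
    between-imputation variance.
    """
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if estimates.shape != ses.shape:
        raise ValueError("estimates and standard errors differ in length")
    m = len(estimates)
    if m < 2:
        raise ValueError("need at least two imputations to pool")
    pooled = estimates.mean()
    within = np.mean(ses**2)
    between = estimates.var(ddof=1)
    total = within + (1 + 1 / m) * between
    return float(pooled), float(np.sqrt(total)), float(total)
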