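"""End-to-end head-to-head validation of the four dementia risk models.

:func:`run_validation` scores a cohort with every requested model, evaluates
Harrell's C per model variant (full / age-only / without-age) at each
prediction horizon with truncation, runs the calibration and recalibration
machinery for models with an absolute-risk equation (the DRS always; CAIDE
only when a score-to-risk mapping is configured), and -- when the cohort has
missing covariates -- multiply imputes and pools by Rubin's rules.

Every adaptation applied along the way (BDSI age extrapolation, DRS
equation stitching, the emulated deprivation index) is logged in the report
metadata so emitted reports are self-documenting, and the whole run is
deterministic given (cohort, options, seed).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import impute as impute_mod
from . import metrics, scores
from .schema import participant_from_row, validate_cohort_frame

DEFAULT_HORIZONS = (2, 5, 10, 15)
CALIBRATION_HORIZON = 10.0


class PipelineError(ValueError):
    pass


@dataclass
class ValidationReport:
    """Per (model, variant, horizon) discrimination plus calibration blocks.

    Contents are plain primitives so a report round-trips exactly through
    its JSON dump.
    """

    rows: list = field(default_factory=list)
    calibration: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def cell(self, model: str, variant: str, horizon) -> dict:
        for row in self.rows:
            if (row["model"], row["variant"], row["horizon"]) == (
                model, variant, float(horizon)
            ):
                return row
        raise KeyError((model, variant, horizon))

    def to_dict(self) -> dict:
        return {"rows": self.rows, "calibration": self.calibration,
                "metadata": self.metadata}

    @classmethod
    def from_dict(cls, payload: dict) -> "ValidationReport":
        return cls(rows=payload["rows"], calibration=payload["calibration"],
                   metadata=payload["metadata"])


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _score_imputation(cohort: pd.DataFrame, models, caide_risk_table,
                      drs_registry, adaptations: set) -> dict:
    """All score components for one completed cohort.

    Returns ``{model: {"full"|"age_only"|"without_age": array, "risk": array}}``.
    """
    registry = drs_registry or scores.default_drs_registry()
    out = {
        model: {v: np.empty(len(cohort)) for v in scores.VARIANTS}
        for model in models
    }
    for model in models:
        out[model]["risk"] = np.full(len(cohort), np.nan)
    participants = [participant_from_row(r) for r in cohort.to_dict("records")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for model in models:
            for i, p in enumerate(participants):
                comp = scores.score_participant(
                    model, p, extrapolate_age=True,
                    adaptation="rotterdam", drs_registry=registry,
                    caide_risk_table=caide_risk_table,
                )
                out[model]["full"][i] = comp.total
                out[model]["age_only"][i] = comp.age_points
                out[model]["without_age"][i] = comp.non_age_points
                if comp.predicted_risk is not None:
                    out[model]["risk"][i] = comp.predicted_risk
            if model == "bdsi":
                ages = cohort["age"].astype(float)
                if (ages < 65).any() or (ages > 79).any():
                    adaptations.add(
                        "bdsi: age component extrapolated outside 65-79 "
                        "(1 point/year)"
                    )
            if model == "drs":
                adaptations.add(
                    "drs: deprivation quintile emulated from the household "
                    "composite (living status, marital status, loneliness)"
                )
                if (cohort["age"].astype(float) >= 80).any() and \
                        "80-95" not in registry:
                    adaptations.add(
                        "drs: 60-79 equation applied to ages >= 80 "
                        "(no 80-95 equation configured)"
                    )
            if model == "anu_adri":
                adaptations.add(
                    "anu_adri: 3-domain social-engagement composite; pesticide "
                    "exposure and cognitive activity omitted"
                )
    return out


def _pool_cells(per_imp: list, m: int) -> dict:
    """Pool one (model, variant, horizon) cell across imputations."""
    degenerate = [c for c in per_imp if c is None or c.degenerate]
    if degenerate and len(degenerate) == len(per_imp):
        return {"c": None, "se": None, "ci_low": None, "ci_high": None,
                "degenerate": True,
                "reason": "constant predictor or no comparable pairs"}
    usable = [c for c in per_imp if c is not None and not c.degenerate]
    cs = np.array([c.c for c in usable])
    ses = np.array([c.se for c in usable])
    if len(usable) == 1:
        c = usable[0]
        return {"c": float(c.c), "se": _nan_none(c.se),
                "ci_low": _nan_none(c.ci_low), "ci_high": _nan_none(c.ci_high),
                "per_imputation": [float(c.c)],
                "degenerate": False, "reason": None}
    if np.isfinite(ses).all():
        pooled, se, _ = impute_mod.pool_rubin(cs, ses)
        lo, hi = pooled - 1.96 * se, pooled + 1.96 * se
    else:
        pooled, se, lo, hi = float(cs.mean()), None, None, None
    return {"c": float(pooled), "se": _nan_none(se), "ci_low": _nan_none(lo),
            "ci_high": _nan_none(hi), "per_imputation": [float(c) for c in cs],
            "degenerate": False, "reason": None}


def _nan_none(x):
    if x is None:
        return None
    x = float(x)
    return None if not np.isfinite(x) else x


def _calibration_block(pred_risk, lp, time, event, horizon, kind,
                       n_bins=10) -> dict:
    """Original + recalibrated calibration results for one model."""

    def as_dict(res: metrics.CalibrationResult) -> dict:
        return {"intercept": res.intercept, "slope": res.slope,
                "bins": [list(b) for b in res.bins], "n_used": res.n_used}

    block: dict = {"horizon": float(horizon), "kind": kind}
    p = np.clip(pred_risk, 1e-12, 1 - 1e-12)
    try:
        block["original"] = as_dict(
            metrics.calibration_intercept_slope(p, time, event, horizon, n_bins)
        )
    except metrics.DegenerateInputError as exc:
        block["original"] = {"error": str(exc)}
    try:
        if kind == "cox":
            updated, s_base, lp_mean = metrics.recalibrate_cox(
                lp, time, event, horizon
            )
            block["baseline_survival_updated"] = s_base
            block["mean_linear_predictor"] = lp_mean
        else:
            updated, delta = metrics.recalibrate_logistic(p, time, event, horizon)
            block["intercept_update"] = delta
        updated = np.clip(updated, 1e-12, 1 - 1e-12)
        block["recalibrated"] = as_dict(
            metrics.calibration_intercept_slope(updated, time, event, horizon,
                                                n_bins)
        )
    except metrics.DegenerateInputError as exc:
        block["recalibrated"] = {"error": str(exc)}
    return block


def run_validation(cohort: pd.DataFrame, *,
                   models=scores.MODELS,
                   horizons=DEFAULT_HORIZONS,
                   variants=scores.VARIANTS,
                   m: int = 5,
                   seed: int = 0,
                   n_bootstrap: int = 200,
                   calibration_horizon: float = CALIBRATION_HORIZON,
                   caide_risk_table: dict | None = None,
                   drs_registry: dict | None = None,
                   age_range: tuple | None = None,
                   provenance: str = "unspecified") -> ValidationReport:
    """Validate the requested models on a cohort table.

    ``age_range=(lo, hi)`` restricts to a model's design ages (the
    whole-cohort run extrapolates/stitches instead).  Missing covariates
    trigger m-fold multiple imputation with Rubin pooling of C-statistics
    on the raw scale.  ``n_bootstrap=0`` skips confidence intervals.
    """
    models = [m_.replace("-", "_") for m_ in models]
    unknown = set(models) - set(scores.MODELS)
    if unknown:
        raise PipelineError(f"unknown model(s): {', '.join(sorted(unknown))}")
    cohort, diagnostics = validate_cohort_frame(cohort)
    if age_range is not None:
        lo, hi = age_range
        cohort = cohort[(cohort["age"].astype(float) >= lo)
                        & (cohort["age"].astype(float) <= hi)]
        cohort = cohort.reset_index(drop=True)
    if len(cohort) == 0:
        raise PipelineError("cohort is empty after exclusions")

    has_missing = cohort[
        [c for c in cohort.columns if c not in ("id", "wave") and
         c not in impute_mod.OUTCOME_COLUMNS]
    ].isna().any().any()
    if has_missing:
        imputation = impute_mod.impute(cohort, m=m, seed=seed)
        completed = imputation.cohorts
    else:
        completed = [cohort]

    adaptations: set = set()
    scored = [
        _score_imputation(df, models, caide_risk_table, drs_registry, adaptations)
        for df in completed
    ]

    time = cohort["time"].astype(float).to_numpy()
    event = (cohort["event"] == "dementia").to_numpy()

    rows = []
    for model in models:
        for variant in variants:
            for horizon in horizons:
                t_h, e_h = metrics.truncate_at_horizon(time, event, horizon)
                per_imp = []
                for k, sc in enumerate(scored):
                    pred = sc[model][variant]
                    try:
                        res = metrics.harrell_c(
                            pred, t_h, e_h, n_bootstrap=n_bootstrap,
                            seed=int(
                                np.random.SeedSequence(
                                    [seed, k, int(round(1000 * horizon))]
                                ).generate_state(1)[0] % (2**31)
                            ),
                        )
                    except metrics.NoComparablePairsError:
                        res = None
                    per_imp.append(res)
                cell = _pool_cells(per_imp, len(scored))
                cell.update({
                    "model": model, "variant": variant, "horizon": float(horizon),
                    "n": int(len(cohort)), "n_events": int(e_h.sum()),
                })
                rows.append(cell)

    calibration = {}
    for model in models:
        risk0 = scored[0][model]["risk"]
        if np.isnan(risk0).all():
            continue
        # average predictions across imputations, then calibrate once
        risk = np.nanmean(np.stack([sc[model]["risk"] for sc in scored]), axis=0)
        if model == "drs":
            lp = np.mean(np.stack([sc[model]["full"] for sc in scored]), axis=0)
            kind = "cox"
        else:
            lp, kind = None, "logistic"
        calibration[model] = _calibration_block(
            risk, lp, time, event, calibration_horizon, kind
        )

    metadata = {
        "seed": seed, "m": len(completed), "n": int(len(cohort)),
        "n_dropped_invalid": len(diagnostics),
        "models": list(models), "variants": list(variants),
        "horizons": [float(h) for h in horizons],
        "n_bootstrap": n_bootstrap,
        "imputed": bool(has_missing),
        "cohort_provenance": provenance,
        "adaptations": sorted(adaptations),
    }
    metadata["config_hash"] = _config_hash(metadata)
    return ValidationReport(rows=rows, calibration=calibration, metadata=metadata)


# --------------------------------------------------------------------------
# sensitivity analyses
# --------------------------------------------------------------------------


def apply_sensitivity(cohort: pd.DataFrame, mode: str):
    """Transform a cohort for one sensitivity analysis.

    ``ad_only``: only Alzheimer's-disease events count (other dementia events
    are censored at diagnosis).  ``landmark_4y``: exclude participants with
    less than 4 years of dementia-free follow-up, clock unchanged.
    ``age_strata_80``: returns the (< 80, >= 80) partition.
    """
    df = cohort.copy()
    if mode == "ad_only":
        if df.loc[df["event"] == "dementia", "ad_subtype"].isna().any():
            raise PipelineError("ad_only sensitivity requires ad_subtype")
        is_ad = df["ad_subtype"].apply(lambda v: bool(v) if v is not None
                                       and v == v else False)
        df["event"] = np.where(
            (df["event"] == "dementia") & is_ad, "dementia", "censored"
        )
        return df
    if mode == "landmark_4y":
        keep = df["time"].astype(float) >= 4.0
        return df[keep].reset_index(drop=True)
    if mode == "age_strata_80":
        young = df[df["age"].astype(float) < 80].reset_index(drop=True)
        old = df[df["age"].astype(float) >= 80].reset_index(drop=True)
        return {"age_lt_80": young, "age_ge_80": old}
    raise PipelineError(f"unknown sensitivity mode '{mode}'")


def run_sensitivity(cohort: pd.DataFrame, mode: str, **kwargs):
    """Run the validation under one sensitivity mode.

    Returns a single report, or a dict of two reports for ``age_strata_80``.
    """
    transformed = apply_sensitivity(cohort, mode)
    if isinstance(transformed, dict):
        out = {}
        for name, stratum in transformed.items():
            if len(stratum) == 0:
                raise PipelineError(f"empty stratum '{name}'")
            out[name] = run_validation(stratum, provenance=f"sensitivity:{mode}",
                                       **kwargs)
        return out
    return run_validation(transformed, provenance=f"sensitivity:{mode}", **kwargs)


# --------------------------------------------------------------------------
# report emission
# --------------------------------------------------------------------------


def emit_report(report: ValidationReport, outdir) -> list:
    """Write the report: a tidy discrimination table, per-model calibration
    bin tables, and a structured JSON dump that parses back to an equal
    report.  Two runs with the same inputs emit byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    disc = outdir / "discrimination.csv"
    cols = ["model", "variant", "horizon", "c", "se", "ci_low", "ci_high",
            "n_events", "n", "degenerate", "reason"]
    with open(disc, "w", encoding="utf-8") as fh:
        fh.write(",".join(cols) + "\n")
        for row in report.rows:
            cells = []
            for c in cols:
                v = row.get(c)
                if v is None:
                    cells.append("NA" if c in ("c", "se", "ci_low", "ci_high")
                                 else "")
                elif isinstance(v, bool):
                    cells.append("1" if v else "0")
                elif isinstance(v, float):
                    cells.append(repr(v))
                else:
                    cells.append(str(v))
            fh.write(",".join(cells) + "\n")
    written.append(disc)

    for model, block in report.calibration.items():
        path = outdir / f"calibration_{model}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("which,mean_predicted,observed,ci_low,ci_high,n\n")
            for which in ("original", "recalibrated"):
                for b in block.get(which, {}).get("bins", []):
                    fh.write(which + "," + ",".join(repr(float(x)) for x in b[:4])
                             + f",{int(b[4])}\n")
        written.append(path)

    dump = outdir / "report.json"
    with open(dump, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(dump)
    return written


def load_report(path) -> ValidationReport:
    """Parse a JSON report dump back into a :class:`ValidationReport`."""
    with open(Path(path), encoding="utf-8") as fh:
        return ValidationReport.from_dict(json.load(fh))
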