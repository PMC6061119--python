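"""Cohort schema, in-memory containers, and delimited-text I/O.

A cohort is a table of baseline covariates plus a right-censored
time-to-dementia outcome, one row per participant.  The canonical in-memory
representation is a :class:`pandas.DataFrame` whose columns are exactly the
schema fields below; missing values are ``NaN``/``None`` in memory and empty
fields on disk.  :class:`Participant` / :class:`Outcome` dataclasses provide a
typed row view used by the scoring functions.

Serialisation conventions: booleans as ``0``/``1``, categories as lowercase
tokens, time in years as floating point.  No dates are stored anywhere;
administrative censoring is expressed directly as a follow-up time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

MISSING = None  # in-memory missing sentinel for row views

WAVES = ("original", "extended")
SEXES = ("female", "male")
SMOKING_LEVELS = ("never", "former", "current")
SOCIAL_LEVELS = ("high", "medium_high", "medium_low", "low")
FISH_LEVELS = ("<=0.25", "0.26-2.0", "2.1-4.0", ">=4.1")
EVENT_LEVELS = ("dementia", "censored")

#: covariate columns in canonical file order, with their kind.
#: kinds: id, category(vocab), continuous, boolean
COVARIATE_FIELDS: dict[str, tuple] = {
    "id": ("id",),
    "wave": ("category", WAVES),
    "age": ("continuous",),
    "sex": ("category", SEXES),
    "education_years": ("continuous",),
    "sbp": ("continuous",),
    "bmi": ("continuous",),
    "total_cholesterol": ("continuous",),
    "hdl_cholesterol": ("continuous",),
    "physical_activity_met_hours": ("continuous",),
    "active_minutes_met4": ("continuous",),
    "diabetes": ("boolean",),
    "stroke": ("boolean",),
    "tia": ("boolean",),
    "atrial_fibrillation": ("boolean",),
    "head_trauma": ("boolean",),
    "depressive_symptoms": ("boolean",),
    "needs_help_finances_medications": ("boolean",),
    "smoking": ("category", SMOKING_LEVELS),
    "alcohol_user": ("boolean",),
    "heavy_drinking": ("boolean",),
    "social_engagement": ("category", SOCIAL_LEVELS),
    "living_with_partner": ("boolean",),
    "married": ("boolean",),
    "lonely": ("boolean",),
    "fish_servings_week": ("category", FISH_LEVELS),
    "uses_antihypertensives": ("boolean",),
    "uses_anxiolytics": ("boolean",),
    "uses_aspirin": ("boolean",),
    "uses_antidepressants": ("boolean",),
    "uses_nsaids": ("boolean",),
    "calendar_year": ("continuous",),
}

OUTCOME_FIELDS: dict[str, tuple] = {
    "time": ("continuous",),
    "event": ("category", EVENT_LEVELS),
    "death": ("boolean",),
    "ad_subtype": ("boolean",),
}

ALL_FIELDS: dict[str, tuple] = {**COVARIATE_FIELDS, **OUTCOME_FIELDS}

#: fields that may never be missing in a valid row
REQUIRED_FIELDS = ("id", "wave", "age", "sex", "time", "event")

BOOLEAN_COLUMNS = [c for c, k in ALL_FIELDS.items() if k[0] == "boolean"]
CONTINUOUS_COLUMNS = [c for c, k in ALL_FIELDS.items() if k[0] == "continuous"]
CATEGORY_COLUMNS = {c: k[1] for c, k in ALL_FIELDS.items() if k[0] == "category"}
COVARIATE_COLUMNS = [c for c in COVARIATE_FIELDS if c != "id"]


class SchemaError(ValueError):
    """File-level schema violation (bad header, duplicate ids)."""


class MissingInputError(ValueError):
    """A scorer input that must be present is missing."""

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"required input '{field}' is missing")


@dataclass(frozen=True)
class RowDiagnostic:
    """One rejected row: which participant, which field, what went wrong."""

    row: int
    id: Optional[str]
    field: str
    message: str


@dataclass
class Outcome:
    """Observed follow-up of one participant.

    ``time`` is years from baseline to the first of dementia diagnosis,
    dementia-free death, loss to follow-up, or administrative end.  ``death``
    marks a dementia-free death (treated as censoring by all metrics);
    ``ad_subtype`` is defined only for dementia events.
    """

    time: float
    event: str  # "dementia" | "censored"
    death: Optional[bool] = None
    ad_subtype: Optional[bool] = None

    @property
    def is_event(self) -> bool:
        return self.event == "dementia"


@dataclass
class Participant:
    """Typed view of one baseline row; any optional field may be missing."""

    id: str
    wave: str
    age: float
    sex: str
    education_years: Optional[float] = None
    sbp: Optional[float] = None
    bmi: Optional[float] = None
    total_cholesterol: Optional[float] = None
    hdl_cholesterol: Optional[float] = None
    physical_activity_met_hours: Optional[float] = None
    active_minutes_met4: Optional[float] = None
    diabetes: Optional[bool] = None
    stroke: Optional[bool] = None
    tia: Optional[bool] = None
    atrial_fibrillation: Optional[bool] = None
    head_trauma: Optional[bool] = None
    depressive_symptoms: Optional[bool] = None
    needs_help_finances_medications: Optional[bool] = None
    smoking: Optional[str] = None
    alcohol_user: Optional[bool] = None
    heavy_drinking: Optional[bool] = None
    social_engagement: Optional[str] = None
    living_with_partner: Optional[bool] = None
    married: Optional[bool] = None
    lonely: Optional[bool] = None
    fish_servings_week: Optional[str] = None
    uses_antihypertensives: Optional[bool] = None
    uses_anxiolytics: Optional[bool] = None
    uses_aspirin: Optional[bool] = None
    uses_antidepressants: Optional[bool] = None
    uses_nsaids: Optional[bool] = None
    calendar_year: Optional[float] = None

    def require(self, *names: str):
        """Return the named fields, raising :class:`MissingInputError` on the
        first one that is missing."""
        out = []
        for name in names:
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise MissingInputError(name)
            out.append(value)
        return out if len(out) > 1 else out[0]


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value == "":
        return True
    return False


def participant_from_row(row) -> Participant:
    """Build a :class:`Participant` from a DataFrame row (Series or mapping)."""
    kwargs = {}
    for f in dc_fields(Participant):
        value = row[f.name] if f.name in row else None
        if _is_missing(value):
            value = None
        elif f.name in BOOLEAN_COLUMNS:
            value = bool(value)
        elif f.name in CONTINUOUS_COLUMNS:
            value = float(value)
        kwargs[f.name] = value
    return Participant(**kwargs)


def outcome_from_row(row) -> Outcome:
    ad = row.get("ad_subtype")
    death = row.get("death")
    return Outcome(
        time=float(row["time"]),
        event=str(row["event"]),
        death=None if _is_missing(death) else bool(death),
        ad_subtype=None if _is_missing(ad) else bool(ad),
    )


def iter_participants(cohort: pd.DataFrame):
    """Yield ``(Participant, Outcome)`` pairs from a cohort table."""
    for row in cohort.to_dict("records"):
        yield participant_from_row(row), outcome_from_row(row)


def empty_cohort() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in ALL_FIELDS})


def _parse_cell(column: str, raw: str, kind: tuple):
    """Parse one serialized cell; raise ValueError with a message on failure."""
    if kind[0] == "id":
        return raw
    if kind[0] == "category":
        if raw not in kind[1]:
            raise ValueError(
                f"value '{raw}' not in vocabulary {{{', '.join(kind[1])}}}"
            )
        return raw
    if kind[0] == "boolean":
        if raw in ("0", "1"):
            return raw == "1"
        raise ValueError(f"boolean must be 0 or 1, got '{raw}'")
    # continuous
    try:
        value = float(raw)
    except ValueError:
        raise ValueError(f"non-parsable numeric '{raw}'") from None
    if not math.isfinite(value):
        raise ValueError(f"non-finite numeric '{raw}'")
    return value


def validate_cohort_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, list[RowDiagnostic]]:
    """Validate an in-memory cohort table row by row.

    Returns the subset of valid rows (original order, reset index) plus a
    diagnostic for every rejected row.  Validation is total: a malformed row
    is always reported, never silently kept or partially parsed.
    """
    unknown = [c for c in df.columns if c not in ALL_FIELDS]
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(sorted(unknown))}")
    missing_cols = [c for c in ALL_FIELDS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing column(s): {', '.join(missing_cols)}")

    diagnostics: list[RowDiagnostic] = []
    keep = np.ones(len(df), dtype=bool)
    records = df.to_dict("records")
    for i, rec in enumerate(records):
        rid = None if _is_missing(rec.get("id")) else str(rec["id"])
        for col, kind in ALL_FIELDS.items():
            value = rec.get(col)
            if _is_missing(value):
                if col in REQUIRED_FIELDS:
                    diagnostics.append(
                        RowDiagnostic(i, rid, col, "required field is missing")
                    )
                    keep[i] = False
                    break
                continue
            try:
                if kind[0] == "category":
                    if value not in kind[1]:
                        raise ValueError(
                            f"value '{value}' not in vocabulary "
                            f"{{{', '.join(kind[1])}}}"
                        )
                elif kind[0] == "boolean":
                    if not isinstance(value, (bool, np.bool_)) and value not in (0, 1):
                        raise ValueError(f"boolean must be 0/1, got '{value}'")
                elif kind[0] == "continuous":
                    v = float(value)
                    if not math.isfinite(v):
                        raise ValueError("non-finite numeric")
            except (ValueError, TypeError) as exc:
                diagnostics.append(RowDiagnostic(i, rid, col, str(exc)))
                keep[i] = False
                break
        else:
            t = rec.get("time")
            if not _is_missing(t) and float(t) <= 0:
                diagnostics.append(
                    RowDiagnostic(i, rid, "time", "follow-up time must be > 0")
                )
                keep[i] = False

    valid = df.loc[keep].reset_index(drop=True)
    ids = valid["id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate participant id(s): {', '.join(sorted(set(dup)))}")
    return valid, diagnostics


def read_cohort(path, schema_version: str = SCHEMA_VERSION):
    """Read a cohort file; return ``(cohort DataFrame, row diagnostics)``.

    The file must be comma-delimited UTF-8 with the exact schema header.
    Missing values are empty fields.  Rows that fail validation are dropped
    and reported; file-level problems raise :class:`SchemaError`.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version '{schema_version}'")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    unknown = [c for c in raw.columns if c not in ALL_FIELDS]
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(sorted(unknown))}")
    missing_cols = [c for c in ALL_FIELDS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing column(s): {', '.join(missing_cols)}")

    diagnostics: list[RowDiagnostic] = []
    parsed_rows: list[dict] = []
    for i, rec in enumerate(raw.to_dict("records")):
        rid = rec.get("id") or None
        out: dict = {}
        ok = True
        for col, kind in ALL_FIELDS.items():
            cell = rec[col]
            if cell == "":
                if col in REQUIRED_FIELDS:
                    diagnostics.append(
                        RowDiagnostic(i, rid, col, "required field is missing")
                    )
                    ok = False
                    break
                out[col] = None
                continue
            try:
                out[col] = _parse_cell(col, cell, kind)
            except ValueError as exc:
                diagnostics.append(RowDiagnostic(i, rid, col, str(exc)))
                ok = False
                break
        if ok and out.get("time") is not None and out["time"] <= 0:
            diagnostics.append(
                RowDiagnostic(i, rid, "time", "follow-up time must be > 0")
            )
            ok = False
        if ok:
            parsed_rows.append(out)

    if parsed_rows:
        cohort = pd.DataFrame(parsed_rows, columns=list(ALL_FIELDS))
    else:
        cohort = empty_cohort()
    ids = cohort["id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate participant id(s): {', '.join(sorted(set(dup)))}")
    return cohort, diagnostics


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table in the canonical column order.

    Booleans become 0/1, missing values empty fields; the output round-trips
    bit-for-bit through :func:`read_cohort`.
    """
    df = cohort.copy()
    for col in ALL_FIELDS:
        if col not in df.columns:
            df[col] = None
    df = df[list(ALL_FIELDS)]

    def fmt(col, value):
        if _is_missing(value):
            return ""
        if col in BOOLEAN_COLUMNS:
            return "1" if bool(value) else "0"
        if col in CONTINUOUS_COLUMNS:
            return repr(float(value))
        return str(value)

    out = pd.DataFrame(
        {col: [fmt(col, v) for v in df[col]] for col in ALL_FIELDS}
    )
    out.to_csv(path, index=False)
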