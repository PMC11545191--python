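"""Cohort data schema, validation, derived covariates, and delimited-file I/O.

The cohort is a per-individual table of the measurements a point-based
heart-age calculator consumes (age, sex, anthropometrics, blood pressure,
fasting lipids and glucose) plus the lifestyle covariates used downstream
(smoking, physical activity, Mediterranean-diet score, alcohol units/week,
social class, education).  All analytes are in mg/dL; no mmol/L conversion
layer is provided.

Rows that violate schema invariants are never dropped silently: validation
routes them to a rejects table with a reason code per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCHEMA_COLUMNS",
    "SchemaError",
    "RiskProfile",
    "CohortTable",
    "compute_bmi",
    "friedewald_ldl",
    "validate_rows",
    "add_derived_covariates",
    "read_cohort",
    "write_cohort",
]

# Validity window of the heart-age scale itself (the study further restricted
# enrolment to ages 20-69; that is an analysis filter, not a schema bound).
SCALE_AGE_MIN = 18.0
SCALE_AGE_MAX = 80.0

# Friedewald LDL estimation is unreliable above this triglyceride level.
FRIEDEWALD_TG_MAX = 400.0

# Mediterranean-diet adherence: score >= 9 on the 14-item questionnaire.
MED_DIET_ADHERENCE_SCORE = 9
# High alcohol intake: >= 14 units/week (women), >= 21 units/week (men).
ALCOHOL_HIGH_FEMALE = 14.0
ALCOHOL_HIGH_MALE = 21.0

SEXES = ("male", "female")
SOCIAL_CLASSES = ("I", "II", "III")
EDUCATION_LEVELS = ("elementary", "high_school", "university")

_NUMERIC_COLS = (
    "age",
    "height_cm",
    "weight_kg",
    "sbp_mmHg",
    "dbp_mmHg",
    "total_chol_mgdl",
    "hdl_mgdl",
    "tg_mgdl",
    "glucose_mgdl",
    "med_diet_score",
    "alcohol_units_week",
)
_OPTIONAL_NUMERIC_COLS = ("waist_cm", "ldl_mgdl")
_BOOL_COLS = ("smoker", "bp_treated", "glucose_treated", "physically_active")

#: Canonical column order of a cohort table.
SCHEMA_COLUMNS = (
    "id",
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    "waist_cm",
    "sbp_mmHg",
    "dbp_mmHg",
    "total_chol_mgdl",
    "hdl_mgdl",
    "ldl_mgdl",
    "tg_mgdl",
    "glucose_mgdl",
    "smoker",
    "bp_treated",
    "glucose_treated",
    "physically_active",
    "med_diet_score",
    "alcohol_units_week",
    "social_class",
    "education",
)

_MANDATORY_COLUMNS = tuple(
    c for c in SCHEMA_COLUMNS if c not in ("waist_cm", "ldl_mgdl")
)


class SchemaError(ValueError):
    """A cohort file or table does not conform to the schema."""


@dataclass
class RiskProfile:
    """One individual's raw measurements and categorical covariates."""

    id: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float
    sbp_mmHg: float
    dbp_mmHg: float
    total_chol_mgdl: float
    hdl_mgdl: float
    tg_mgdl: float
    glucose_mgdl: float
    smoker: bool
    physically_active: bool
    med_diet_score: int
    alcohol_units_week: float
    social_class: str
    education: str
    waist_cm: float | None = None
    ldl_mgdl: float | None = None
    bp_treated: bool = False
    glucose_treated: bool = False


@dataclass
class CohortTable:
    """Validated cohort rows plus the rejects report and provenance."""

    data: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"])
    )
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def profiles(self):
        """Iterate rows as :class:`RiskProfile` objects."""
        for _, row in self.data.iterrows():
            kwargs = {c: row[c] for c in SCHEMA_COLUMNS if c in row.index}
            for opt in ("waist_cm", "ldl_mgdl"):
                if opt in kwargs and pd.isna(kwargs[opt]):
                    kwargs[opt] = None
            yield RiskProfile(**kwargs)


def compute_bmi(weight_kg, height_cm):
    """Body-mass index in kg/m² from weight in kg and height in cm.

    Accepts scalars or arrays; raises for nonpositive inputs.
    """
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be strictly positive")
    out = w / (h / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def friedewald_ldl(total_chol_mgdl, hdl_mgdl, tg_mgdl):
    """Estimate LDL cholesterol as TC − HDL − TG/5 (all mg/dL).

    Returns ``(ldl, valid)``.  The estimate is flagged invalid when
    triglycerides exceed 400 mg/dL (the formula's reliability bound) or when
    the computed LDL is not positive; the raw value is still returned, never
    clamped, so it can be audited.
    """
    tc = np.asarray(total_chol_mgdl, dtype=float)
    hdl = np.asarray(hdl_mgdl, dtype=float)
    tg = np.asarray(tg_mgdl, dtype=float)
    ldl = tc - hdl - tg / 5.0
    valid = (tg <= FRIEDEWALD_TG_MAX) & (ldl > 0)
    if ldl.ndim == 0:
        return float(ldl), bool(valid)
    return ldl, valid


def _reject_reasons(df: pd.DataFrame) -> pd.Series:
    """Per-row reject reason ('' when the row is valid)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        mask = mask & (reasons == "")
        reasons[mask] = reason

    num = {c: pd.to_numeric(df[c], errors="coerce") for c in _NUMERIC_COLS}
    bad_numeric = pd.Series(False, index=df.index)
    for c in _NUMERIC_COLS:
        bad_numeric |= num[c].isna()
    flag(bad_numeric, "unparseable or missing numeric field")
    flag(
        (num["age"] < SCALE_AGE_MIN) | (num["age"] > SCALE_AGE_MAX),
        "outside scale validity 18-80",
    )
    flag(num["hdl_mgdl"] <= 0, "nonpositive HDL")
    for c, reason in [
        ("total_chol_mgdl", "nonpositive total cholesterol"),
        ("tg_mgdl", "nonpositive triglycerides"),
        ("glucose_mgdl", "nonpositive glucose"),
    ]:
        flag(num[c] <= 0, reason)
    flag((num["height_cm"] <= 0) | (num["weight_kg"] <= 0), "nonpositive anthropometry")
    flag(num["sbp_mmHg"] < num["dbp_mmHg"], "systolic below diastolic")
    flag(~df["sex"].isin(SEXES), "unknown sex")
    flag(~df["social_class"].isin(SOCIAL_CLASSES), "unknown social class")
    flag(~df["education"].isin(EDUCATION_LEVELS), "unknown education level")
    flag(
        (num["med_diet_score"] < 0) | (num["med_diet_score"] > 14),
        "diet score outside 0-14",
    )
    flag(num["alcohol_units_week"] < 0, "negative alcohol units")
    return reasons


def validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw cohort frame into (valid, rejects-with-reason).

    Raises :class:`SchemaError` for a missing mandatory column or duplicate
    ids; individual bad rows are routed to the rejects frame.
    """
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.copy()
    for opt in _OPTIONAL_NUMERIC_COLS:
        if opt not in df.columns:
            df[opt] = np.nan
    df["id"] = df["id"].astype(str)
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].unique()
        raise SchemaError(f"duplicate ids: {', '.join(map(str, dupes[:5]))}")

    reasons = _reject_reasons(df)
    ok = reasons == ""
    rejects = df.loc[~ok].copy()
    rejects["reason"] = reasons[~ok]

    valid = df.loc[ok].copy()
    for c in _NUMERIC_COLS + _OPTIONAL_NUMERIC_COLS:
        valid[c] = pd.to_numeric(valid[c], errors="coerce")
    valid["med_diet_score"] = valid["med_diet_score"].astype(int)
    for c in _BOOL_COLS:
        valid[c] = _coerce_bool(valid[c])
    return valid[list(SCHEMA_COLUMNS)].reset_index(drop=True), rejects.reset_index(
        drop=True
    )


def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "True": True, "False": False,
        1: True, 0: False, 1.0: True, 0.0: False, True: True, False: False,
    }
    out = s.map(lambda v: mapping.get(v if not isinstance(v, str) else v.strip().lower()))
    if out.isna().any():
        bad = s[out.isna()].iloc[0]
        raise SchemaError(f"unparseable boolean value: {bad!r}")
    return out.astype(bool)


def add_derived_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns: BMI, Friedewald LDL, flags.

    Adds ``bmi_kgm2``, fills missing ``ldl_mgdl`` by the Friedewald formula,
    and appends ``ldl_valid`` (usable for LDL-based indices), mediterranean
    diet adherence (score ≥ 9) and sex-specific high-alcohol flags.
    """
    out = df.copy()
    out["bmi_kgm2"] = compute_bmi(out["weight_kg"].to_numpy(), out["height_cm"].to_numpy())
    fw_ldl, fw_valid = friedewald_ldl(
        out["total_chol_mgdl"].to_numpy(),
        out["hdl_mgdl"].to_numpy(),
        out["tg_mgdl"].to_numpy(),
    )
    measured = out["ldl_mgdl"].notna()
    out["ldl_mgdl"] = np.where(measured, out["ldl_mgdl"], fw_ldl)
    # A directly measured LDL is trusted; a derived one only inside the
    # formula's validity region.
    out["ldl_valid"] = np.where(measured, out["ldl_mgdl"] > 0, fw_valid)
    out["med_diet_adherent"] = out["med_diet_score"] >= MED_DIET_ADHERENCE_SCORE
    thr = np.where(out["sex"] == "female", ALCOHOL_HIGH_FEMALE, ALCOHOL_HIGH_MALE)
    out["high_alcohol"] = out["alcohol_units_week"] >= thr
    return out


def _load_column_map(column_map) -> Mapping[str, str] | None:
    if column_map is None or isinstance(column_map, Mapping):
        return column_map
    with open(column_map) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, Mapping):
        raise SchemaError("column map config must be a mapping of header -> field")
    return loaded


def read_cohort(
    path,
    column_map=None,
    delimiter: str = ",",
    na_token: str = "",
) -> CohortTable:
    """Read and validate a delimited cohort file.

    Parameters
    ----------
    path:
        CSV/TSV file with a header row.
    column_map:
        Optional mapping (dict or YAML file path) from the file's header
        names onto schema field names, so arbitrary occupational-health
        exports can be ingested.
    delimiter, na_token:
        Dialect; the default NA token is the empty field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, na_values=[na_token], keep_default_na=False
    )
    cmap = _load_column_map(column_map)
    if cmap:
        raw = raw.rename(columns=dict(cmap))
    valid, rejects = validate_rows(raw)
    return CohortTable(valid, rejects, provenance={"source": str(path)})


def write_cohort(table: CohortTable, path, delimiter: str = ",", na_token: str = "") -> None:
    """Write a cohort table so that :func:`read_cohort` round-trips it.

    Optional fields that are absent are emitted as the NA token; booleans are
    serialized as ``true``/``false``.
    """
    df = table.data.copy()
    for c in _BOOL_COLS:
        if c in df.columns:
            df[c] = df[c].map({True: "true", False: "false"})
    df = df[[c for c in SCHEMA_COLUMNS if c in df.columns]]
    df.to_csv(path, sep=delimiter, index=False, na_rep=na_token)


def write_rejects(table: CohortTable, path, delimiter: str = ",") -> None:
    """Write the rejects report (original fields plus a reason column)."""
    table.rejects.to_csv(path, sep=delimiter, index=False)
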