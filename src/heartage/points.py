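"""Sex-specific point-based heart-age calculator.

Six risk factors — total cholesterol, HDL-c, fasting glucose, smoking, BMI,
and blood pressure — each contribute an integer number of points read from a
banded table (shipped as a versioned YAML asset, so the table is data, not
code).  The summed points shift the chronological age: the shift is clamped
to [−20, +19] years, the clamped shift is the ALLY statistic ("avoidable lost
life years" heart age, HA − CA), and ALLY ≥ 17 years defines a *high* ALLY
heart age.

Banding conventions
-------------------
Printed integer bands are normalized to half-open real intervals (e.g. the
band pair "130–145 / 146–160" becomes [130, 146) / [146, 161)) so continuous
laboratory values never fall between bands.  Blood pressure is banded per
pressure — systolic and diastolic each against their own thresholds — and the
higher-points band of the two is used, the usual convention for discordant
pressures.  Being under treatment for glucose or blood pressure overrides the
measured value with that factor's maximum points.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml

from .schema import RiskProfile, compute_bmi

__all__ = [
    "FACTORS",
    "PointsTable",
    "HeartAgeResult",
    "load_points_table",
    "lookup_points",
    "score_bp_band",
    "compute_heart_age",
    "classify_high_ally",
    "score_cohort",
]

FACTORS = ("total_chol", "hdl", "glucose", "smoker", "bmi", "bp")


@dataclass(frozen=True)
class _BandedFactor:
    """Ordered half-open bands covering (0, ∞): edges split, points per band."""

    edges: tuple[float, ...]   # interior band boundaries, ascending
    points: tuple[int, ...]    # len(edges) + 1 entries

    def lookup(self, value):
        value = np.asarray(value, dtype=float)
        idx = np.searchsorted(np.asarray(self.edges), value, side="right")
        pts = np.asarray(self.points)[idx]
        return int(pts) if pts.ndim == 0 else pts

    @property
    def min_points(self) -> int:
        return min(self.points)

    @property
    def max_points(self) -> int:
        return max(self.points)


def _banded(bands) -> _BandedFactor:
    edges, points = [], []
    prev_upper = 0.0
    for i, (lo, hi, pts) in enumerate(bands):
        lo = 0.0 if lo is None else float(lo)
        if lo != prev_upper:
            raise ValueError(f"bands not contiguous at {lo}")
        if hi is None and i != len(bands) - 1:
            raise ValueError("only the last band may be unbounded")
        prev_upper = np.inf if hi is None else float(hi)
        points.append(int(pts))
        if hi is not None:
            edges.append(float(hi))
    if prev_upper != np.inf:
        raise ValueError("last band must be unbounded above")
    return _BandedFactor(tuple(edges), tuple(points))


@dataclass(frozen=True)
class _SexTable:
    total_chol: _BandedFactor
    hdl: _BandedFactor
    glucose: _BandedFactor
    glucose_treated_points: int
    smoker_yes: int
    smoker_no: int
    bmi: _BandedFactor
    sbp: _BandedFactor
    dbp: _BandedFactor
    bp_treated_points: int


class PointsTable:
    """The full sex-specific band→points mapping plus clamp and cut-offs."""

    def __init__(self, spec: dict):
        self.version = spec.get("version", 0)
        self.clamp_lower = int(spec["clamp"]["lower"])
        self.clamp_upper = int(spec["clamp"]["upper"])
        self.high_ally_cutoff = float(spec["high_ally_cutoff"])
        self._sex: dict[str, _SexTable] = {}
        for sex in ("male", "female"):
            s = spec[sex]
            self._sex[sex] = _SexTable(
                total_chol=_banded(s["total_chol"]["bands"]),
                hdl=_banded(s["hdl"]["bands"]),
                glucose=_banded(s["glucose"]["bands"]),
                glucose_treated_points=int(s["glucose"]["treated_points"]),
                smoker_yes=int(s["smoker"]["yes"]),
                smoker_no=int(s["smoker"]["no"]),
                bmi=_banded(s["bmi"]["bands"]),
                sbp=_banded(s["bp"]["sbp_bands"]),
                dbp=_banded(s["bp"]["dbp_bands"]),
                bp_treated_points=int(s["bp"]["treated_points"]),
            )

    def sex_table(self, sex: str) -> _SexTable:
        try:
            return self._sex[sex]
        except KeyError:
            raise ValueError(f"unknown sex: {sex!r}") from None

    def factor_min(self, sex: str, factor: str) -> int:
        t = self.sex_table(sex)
        if factor == "smoker":
            return min(t.smoker_yes, t.smoker_no)
        if factor == "bp":
            return min(t.sbp.min_points, t.dbp.min_points)
        return getattr(t, factor).min_points

    def factor_max(self, sex: str, factor: str) -> int:
        t = self.sex_table(sex)
        if factor == "smoker":
            return max(t.smoker_yes, t.smoker_no)
        if factor == "bp":
            # the per-pressure max-rule makes the factor max the larger of the two
            return max(t.sbp.max_points, t.dbp.max_points)
        return getattr(t, factor).max_points

    def minima_sum(self, sex: str) -> int:
        return sum(self.factor_min(sex, f) for f in FACTORS)

    def maxima_sum(self, sex: str) -> int:
        return sum(self.factor_max(sex, f) for f in FACTORS)


@lru_cache(maxsize=1)
def load_points_table() -> PointsTable:
    """Load the packaged points-table asset."""
    ref = importlib.resources.files("heartage") / "assets" / "points_table.yaml"
    with ref.open() as fh:
        return PointsTable(yaml.safe_load(fh))


def lookup_points(sex, factor, value, treated=False, table: PointsTable | None = None):
    """Points for a single factor value.

    For ``factor='bp'``, ``value`` is a ``(sbp, dbp)`` pair.  ``treated``
    applies only to glucose and blood pressure and returns that factor's
    maximum points regardless of the measured value.
    """
    table = table or load_points_table()
    t = table.sex_table(sex)
    if factor == "total_chol":
        return t.total_chol.lookup(value)
    if factor == "hdl":
        return t.hdl.lookup(value)
    if factor == "glucose":
        return t.glucose_treated_points if treated else t.glucose.lookup(value)
    if factor == "smoker":
        return t.smoker_yes if value else t.smoker_no
    if factor == "bmi":
        return t.bmi.lookup(value)
    if factor == "bp":
        sbp, dbp = value
        return score_bp_band(sex, sbp, dbp, treated, table)
    raise ValueError(f"unknown factor: {factor!r}")


def score_bp_band(sex, sbp, dbp, treated=False, table: PointsTable | None = None):
    """Blood-pressure points: worse (higher-points) of the SBP and DBP bands."""
    table = table or load_points_table()
    t = table.sex_table(sex)
    if treated:
        return t.bp_treated_points
    return max(t.sbp.lookup(sbp), t.dbp.lookup(dbp))


@dataclass
class HeartAgeResult:
    """Per-factor points and the resulting heart age for one individual."""

    per_factor_points: dict[str, int]
    total_points: int          # raw sum, before clamping
    delta_clamped: float       # years added to chronological age
    heart_age: float
    ally: float                # HA − CA; negative means a younger heart
    high_ally: bool


def classify_high_ally(ally, table: PointsTable | None = None):
    """High ALLY heart age: the HA−CA gap is at or above the 17-year cut-off."""
    cutoff = (table or load_points_table()).high_ally_cutoff
    a = np.asarray(ally, dtype=float)
    out = a >= cutoff
    return bool(out) if out.ndim == 0 else out


def compute_heart_age(profile: RiskProfile, table: PointsTable | None = None) -> HeartAgeResult:
    """Score one individual: six factor points, clamp, ALLY, high-ALLY flag."""
    table = table or load_points_table()
    if not (18.0 <= profile.age <= 80.0):
        raise ValueError(
            f"age {profile.age} outside the scale's validity window 18-80"
        )
    bmi = compute_bmi(profile.weight_kg, profile.height_cm)
    pts = {
        "total_chol": lookup_points(profile.sex, "total_chol", profile.total_chol_mgdl, table=table),
        "hdl": lookup_points(profile.sex, "hdl", profile.hdl_mgdl, table=table),
        "glucose": lookup_points(
            profile.sex, "glucose", profile.glucose_mgdl, profile.glucose_treated, table
        ),
        "smoker": lookup_points(profile.sex, "smoker", profile.smoker, table=table),
        "bmi": lookup_points(profile.sex, "bmi", bmi, table=table),
        "bp": score_bp_band(
            profile.sex, profile.sbp_mmHg, profile.dbp_mmHg, profile.bp_treated, table
        ),
    }
    total = int(sum(pts.values()))
    delta = float(np.clip(total, table.clamp_lower, table.clamp_upper))
    ha = profile.age + delta
    return HeartAgeResult(
        per_factor_points=pts,
        total_points=total,
        delta_clamped=delta,
        heart_age=ha,
        ally=delta,
        high_ally=classify_high_ally(delta, table),
    )


def score_cohort(df: pd.DataFrame, table: PointsTable | None = None) -> pd.DataFrame:
    """Vectorized scoring of a validated cohort frame.

    Appends ``points_*`` per factor, ``total_points``, ``heart_age``, ``ally``
    and ``high_ally`` columns.  Requires a ``bmi_kgm2`` column (see
    :func:`heartage.schema.add_derived_covariates`); computes it if absent.
    """
    table = table or load_points_table()
    out = df.copy()
    if "bmi_kgm2" not in out.columns:
        out["bmi_kgm2"] = compute_bmi(
            out["weight_kg"].to_numpy(), out["height_cm"].to_numpy()
        )
    bad_age = (out["age"] < 18.0) | (out["age"] > 80.0)
    if bad_age.any():
        raise ValueError(
            f"{int(bad_age.sum())} rows outside the scale's validity window 18-80"
        )

    n = len(out)
    cols = {f: np.zeros(n, dtype=int) for f in FACTORS}
    for sex in ("male", "female"):
        m = (out["sex"] == sex).to_numpy()
        if not m.any():
            continue
        t = table.sex_table(sex)
        cols["total_chol"][m] = t.total_chol.lookup(out.loc[m, "total_chol_mgdl"].to_numpy())
        cols["hdl"][m] = t.hdl.lookup(out.loc[m, "hdl_mgdl"].to_numpy())
        glu = t.glucose.lookup(out.loc[m, "glucose_mgdl"].to_numpy())
        glu = np.where(out.loc[m, "glucose_treated"].to_numpy(bool), t.glucose_treated_points, glu)
        cols["glucose"][m] = glu
        cols["smoker"][m] = np.where(
            out.loc[m, "smoker"].to_numpy(bool), t.smoker_yes, t.smoker_no
        )
        cols["bmi"][m] = t.bmi.lookup(out.loc[m, "bmi_kgm2"].to_numpy())
        bp = np.maximum(
            t.sbp.lookup(out.loc[m, "sbp_mmHg"].to_numpy()),
            t.dbp.lookup(out.loc[m, "dbp_mmHg"].to_numpy()),
        )
        bp = np.where(out.loc[m, "bp_treated"].to_numpy(bool), t.bp_treated_points, bp)
        cols["bp"][m] = bp

    for f in FACTORS:
        out[f"points_{f}"] = cols[f]
    total = sum(cols.values())
    out["total_points"] = total
    delta = np.clip(total, table.clamp_lower, table.clamp_upper).astype(float)
    out["ally"] = delta
    out["heart_age"] = out["age"].to_numpy() + delta
    out["high_ally"] = delta >= table.high_ally_cutoff
    return out
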