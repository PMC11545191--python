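"""Atherogenic lipid indices and their risk categories.

Three unitless ratios of lipid fractions serve as atherosclerosis-risk
proxies: TC/HDL-c, LDL-c/HDL-c, and TG/HDL-c.  Risk categories follow the
usual clinical cut-offs: TC/HDL is three-level and sex-specific (women:
low < 4.5, moderate 4.5–7, high > 7; men: low < 5, moderate 5–9, high > 9);
LDL/HDL and TG/HDL are binary with the high category at ratio ≥ 3.  The
boundary itself is assigned to the higher category throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import RiskProfile

__all__ = [
    "AtherogenicAssessment",
    "compute_indices",
    "categorize_tc_hdl",
    "categorize_ldl_hdl",
    "categorize_tg_hdl",
    "index_cohort",
]

TC_HDL_CUTS = {"female": (4.5, 7.0), "male": (5.0, 9.0)}
LDL_HDL_HIGH = 3.0
TG_HDL_HIGH = 3.0

TC_HDL_LEVELS = ("low", "moderate", "high")
BINARY_LEVELS = ("normal", "high")


@dataclass
class AtherogenicAssessment:
    tc_hdl: float
    tg_hdl: float
    tc_hdl_category: str
    tg_hdl_category: str
    ldl_hdl: float | None = None      # None when LDL is missing or invalid
    ldl_hdl_category: str | None = None


def categorize_tc_hdl(value, sex: str) -> str:
    """Three-level TC/HDL risk category with sex-specific cut-offs."""
    if sex not in TC_HDL_CUTS:
        raise ValueError(f"unknown sex: {sex!r}")
    lo, hi = TC_HDL_CUTS[sex]
    if value < lo:
        return "low"
    return "moderate" if value <= hi else "high"


def categorize_ldl_hdl(value) -> str:
    return "high" if value >= LDL_HDL_HIGH else "normal"


def categorize_tg_hdl(value) -> str:
    return "high" if value >= TG_HDL_HIGH else "normal"


def compute_indices(profile: RiskProfile, ldl_valid: bool | None = None) -> AtherogenicAssessment:
    """The three ratios plus categories for one individual.

    The LDL-based index is reported only when an LDL value is available and
    (if provided) flagged valid; otherwise it is None and the profile is
    excluded from LDL-based analyses, not from the cohort.
    """
    if profile.hdl_mgdl <= 0:
        raise ValueError("HDL must be strictly positive to form ratios")
    tc_hdl = profile.total_chol_mgdl / profile.hdl_mgdl
    tg_hdl = profile.tg_mgdl / profile.hdl_mgdl
    res = AtherogenicAssessment(
        tc_hdl=tc_hdl,
        tg_hdl=tg_hdl,
        tc_hdl_category=categorize_tc_hdl(tc_hdl, profile.sex),
        tg_hdl_category=categorize_tg_hdl(tg_hdl),
    )
    usable = profile.ldl_mgdl is not None and (ldl_valid is None or ldl_valid)
    if usable and profile.ldl_mgdl > 0:
        res.ldl_hdl = profile.ldl_mgdl / profile.hdl_mgdl
        res.ldl_hdl_category = categorize_ldl_hdl(res.ldl_hdl)
    return res


def index_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized version: append index and category columns to a cohort frame.

    Expects ``ldl_mgdl``/``ldl_valid`` columns (see
    :func:`heartage.schema.add_derived_covariates`); rows without a valid LDL
    get NA for the LDL-based index and its category.
    """
    out = df.copy()
    hdl = out["hdl_mgdl"].to_numpy(float)
    if np.any(hdl <= 0):
        raise ValueError("HDL must be strictly positive to form ratios")
    out["tc_hdl"] = out["total_chol_mgdl"].to_numpy(float) / hdl
    out["tg_hdl"] = out["tg_mgdl"].to_numpy(float) / hdl

    lo = np.where(out["sex"] == "female", TC_HDL_CUTS["female"][0], TC_HDL_CUTS["male"][0])
    hi = np.where(out["sex"] == "female", TC_HDL_CUTS["female"][1], TC_HDL_CUTS["male"][1])
    v = out["tc_hdl"].to_numpy(float)
    out["tc_hdl_category"] = np.select([v < lo, v <= hi], ["low", "moderate"], "high")
    out["tg_hdl_category"] = np.where(out["tg_hdl"] >= TG_HDL_HIGH, "high", "normal")

    ldl_ok = out["ldl_mgdl"].notna()
    if "ldl_valid" in out.columns:
        ldl_ok &= out["ldl_valid"].fillna(False).astype(bool)
    ratio = out["ldl_mgdl"].to_numpy(float) / hdl
    out["ldl_hdl"] = np.where(ldl_ok, ratio, np.nan)
    out["ldl_hdl_category"] = pd.Series(
        np.where(ratio >= LDL_HDL_HIGH, "high", "normal"), index=out.index
    ).where(ldl_ok)
    return out
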