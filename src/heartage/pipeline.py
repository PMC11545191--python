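"""Pipeline orchestration: read/simulate → score → indices → analyze → render.

One :class:`RunConfig` drives a reproducible run: a single seed feeds every
random stage, and a manifest (config, seed, package version, SHA-256 of each
output) is written alongside the outputs so identical runs are verifiable
byte-for-byte.

The rendered report mirrors the standard presentation of this kind of
study: mean ALLY by index category and sex; index and ALLY means by age
band; prevalence of high ALLY by index category; age-stratified odds-ratio
table; AUC table; and the cut-off/sensitivity/specificity/Youden table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .indices import index_cohort
from .points import load_points_table, score_cohort
from .schema import CohortTable, add_derived_covariates, read_cohort, write_rejects
from .simulate import default_config, generate_cohort
from .stats import bivariate_tables, roc_curve, stratified_analysis

__all__ = ["RunConfig", "run_pipeline", "render_tables", "prepare_scored_cohort"]

log = logging.getLogger("heartage")

INDEX_FAMILIES = {
    "tc_hdl": ("low", "moderate", "high"),
    "ldl_hdl": ("normal", "high"),
    "tg_hdl": ("normal", "high"),
}

#: Covariates and reference levels of the age-stratified regression: women,
#: class I, university, non-smoker, active, diet-adherent, non-drinker and
#: the low/normal index categories are the OR=1 rows.
REGRESSION_COVARIATES = [
    "sex",
    "social_class",
    "education",
    "smoker",
    "physically_active",
    "med_diet_adherent",
    "alcohol_drinker",
    "tc_hdl_category",
    "ldl_hdl_category",
    "tg_hdl_category",
]
REGRESSION_REFERENCES = {
    "sex": "female",
    "social_class": "I",
    "education": "university",
    "smoker": "False",
    "physically_active": "True",
    "med_diet_adherent": "True",
    "alcohol_drinker": "False",
    "tc_hdl_category": "low",
    "ldl_hdl_category": "normal",
    "tg_hdl_category": "normal",
}


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``input_path`` (a cohort CSV) or ``simulate`` (generator
    sizes, optionally ``n_male``/``n_female``/``latent_effect``) must be
    given.  ``missing_ldl`` chooses between per-analysis exclusion of rows
    without a valid LDL (default) and complete-case analysis.
    """

    out_dir: str | Path
    seed: int = 0
    input_path: str | Path | None = None
    simulate: dict | None = None
    column_map: dict | str | None = None
    stages: tuple[str, ...] = ("score", "indices", "analyze", "render")
    missing_ldl: str = "per_analysis"   # or "complete_case"
    strata: list[tuple[float, float]] = field(
        default_factory=lambda: [(20, 30), (30, 40), (40, 50), (50, 60), (60, 70)]
    )
    # Covariates of the age-stratified regression.  Note: under the printed
    # points table a non-smoker cannot reach the 17-year cut-off (max 15
    # points without smoking), so on table-scored outcomes the smoker term is
    # quasi-separated by construction; drop it from this list to obtain
    # converging stratified fits.
    regression_covariates: list[str] = field(
        default_factory=lambda: list(REGRESSION_COVARIATES)
    )

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of 'input_path' and 'simulate' must be configured"
            )
        if self.missing_ldl not in ("per_analysis", "complete_case"):
            raise ValueError("missing_ldl must be 'per_analysis' or 'complete_case'")


def prepare_scored_cohort(table: CohortTable) -> pd.DataFrame:
    """Derived covariates + heart-age score + atherogenic indices, one frame."""
    df = add_derived_covariates(table.data)
    df = score_cohort(df)
    df = index_cohort(df)
    df["alcohol_drinker"] = df["alcohol_units_week"] > 0
    return df


def _fmt_ci(v, lo, hi, nd=2):
    return f"{v:.{nd}f} ({lo:.{nd}f}-{hi:.{nd}f})"


def _group_pvalue(groups: list[np.ndarray]) -> float:
    groups = [g for g in groups if len(g) > 1]
    if len(groups) < 2:
        return np.nan
    if len(groups) == 2:
        return float(sps.ttest_ind(*groups, equal_var=False).pvalue)
    return float(sps.f_oneway(*groups).pvalue)


def render_tables(
    df: pd.DataFrame,
    out_dir: Path,
    strata,
    seed: int,
    regression_covariates: list[str] | None = None,
) -> dict[str, Path]:
    """Write the six report tables plus per-index ROC operating points."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # --- mean ALLY by index category and sex -------------------------------
    rows = []
    for idx, levels in INDEX_FAMILIES.items():
        for sex in ("male", "female"):
            sub = df[(df["sex"] == sex) & df[f"{idx}_category"].notna()]
            vals = [sub.loc[sub[f"{idx}_category"] == lv, "ally"].to_numpy() for lv in levels]
            p = _group_pvalue(vals)
            for lv, v in zip(levels, vals):
                rows.append(
                    {
                        "index": idx, "category": lv, "sex": sex,
                        "n": len(v),
                        "mean_ally": v.mean() if len(v) else np.nan,
                        "sd_ally": v.std(ddof=1) if len(v) > 1 else np.nan,
                        "p": p,
                    }
                )
    _write(written, "table3_ally_by_index", pd.DataFrame(rows), out_dir)

    # --- index and ALLY means by age band ----------------------------------
    rows = []
    for sex in ("male", "female"):
        for lo, hi in strata:
            sub = df[(df["sex"] == sex) & (df["age"] >= lo) & (df["age"] < hi)]
            row = {"sex": sex, "age_band": f"{int(lo)}-{int(hi)}", "n": len(sub)}
            for col in ("tc_hdl", "ldl_hdl", "tg_hdl", "ally"):
                v = sub[col].dropna()
                row[f"mean_{col}"] = v.mean() if len(v) else np.nan
                row[f"sd_{col}"] = v.std(ddof=1) if len(v) > 1 else np.nan
            rows.append(row)
    _write(written, "table4_by_age_band", pd.DataFrame(rows), out_dir)

    # --- prevalence of high ALLY by index category -------------------------
    rows = []
    for idx, levels in INDEX_FAMILIES.items():
        for sex in ("male", "female"):
            sub = df[(df["sex"] == sex) & df[f"{idx}_category"].notna()]
            tab = pd.crosstab(sub[f"{idx}_category"], sub["high_ally"])
            if tab.shape == (len(levels), 2) and (
                sps.contingency.expected_freq(tab.to_numpy()) >= 5
            ).all():
                _, p, _, _ = sps.chi2_contingency(tab.to_numpy(), correction=False)
            elif tab.shape == (2, 2):
                _, p = sps.fisher_exact(tab.to_numpy())
            else:
                p = np.nan
            for lv in levels:
                g = sub[sub[f"{idx}_category"] == lv]
                rows.append(
                    {
                        "index": idx, "category": lv, "sex": sex, "n": len(g),
                        "pct_high_ally": 100.0 * g["high_ally"].mean() if len(g) else np.nan,
                        "p": p,
                    }
                )
    _write(written, "table5_high_ally_prevalence", pd.DataFrame(rows), out_dir)

    # --- age-stratified odds ratios ----------------------------------------
    reg = df
    if reg["ldl_hdl_category"].isna().any():
        n_drop = int(reg["ldl_hdl_category"].isna().sum())
        log.info("dropping %d rows without valid LDL from the regression", n_drop)
        reg = reg[reg["ldl_hdl_category"].notna()]
    covs = regression_covariates or REGRESSION_COVARIATES
    refs = {c: REGRESSION_REFERENCES[c] for c in covs if c in REGRESSION_REFERENCES}
    fits = stratified_analysis(reg, "high_ally", covs, refs, strata)
    rows = []
    for band, fit in fits.items():
        ors = fit.odds_ratios()
        for _, r in ors.iterrows():
            rows.append(
                {
                    "age_band": band, "term": r["term"],
                    "or": r["or"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                    "or_ci": _fmt_ci(r["or"], r["ci_low"], r["ci_high"]),
                }
            )
    _write(
        written,
        "table6_stratified_or",
        pd.DataFrame(rows, columns=["age_band", "term", "or", "ci_low", "ci_high", "or_ci"]),
        out_dir,
    )

    # --- AUC and cut-off tables --------------------------------------------
    auc_rows, cut_rows = [], []
    for idx in INDEX_FAMILIES:
        for sex in ("male", "female"):
            sub = df[(df["sex"] == sex) & df[idx].notna()]
            if sub["high_ally"].nunique() < 2:
                log.warning("ROC skipped for %s/%s: single-class outcome", idx, sex)
                continue
            roc = roc_curve(sub[idx].to_numpy(), sub["high_ally"].to_numpy(int))
            auc_rows.append(
                {
                    "index": idx, "sex": sex,
                    "auc": roc.auc, "ci_low": roc.auc_ci[0], "ci_high": roc.auc_ci[1],
                    "auc_ci": _fmt_ci(roc.auc, *roc.auc_ci, nd=3),
                }
            )
            cut_rows.append(
                {
                    "index": idx, "sex": sex,
                    "cutoff": roc.best_cutoff,
                    "sensitivity_pct": 100.0 * roc.best_sensitivity,
                    "specificity_pct": 100.0 * roc.best_specificity,
                    "youden_j": roc.youden_j,
                }
            )
            pts = pd.DataFrame(
                {
                    "threshold": roc.thresholds,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                }
            )
            if len(pts) > 512:   # keep exported curves compact
                keep = np.unique(
                    np.linspace(0, len(pts) - 1, 512).round().astype(int)
                )
                pts = pts.iloc[keep]
            _write(written, f"roc_points_{idx}_{sex}", pts, out_dir)
    _write(written, "table7_auc", pd.DataFrame(auc_rows), out_dir)
    _write(written, "table8_cutoffs", pd.DataFrame(cut_rows), out_dir)

    # --- sex-wise descriptives (population characteristics) ----------------
    rep = bivariate_tables(
        df,
        "sex",
        continuous=[
            "age", "height_cm", "weight_kg", "bmi_kgm2", "sbp_mmHg", "dbp_mmHg",
            "total_chol_mgdl", "hdl_mgdl", "ldl_mgdl", "tg_mgdl", "glucose_mgdl",
        ],
        categorical=[
            "social_class", "education", "smoker", "physically_active",
            "med_diet_adherent", "alcohol_drinker",
        ],
    )
    _write(written, "table2_characteristics_continuous", rep.continuous, out_dir)
    _write(written, "table2_characteristics_categorical", rep.categorical, out_dir)
    return written


def _write(written: dict, name: str, frame: pd.DataFrame, out_dir: Path) -> None:
    path = out_dir / f"{name}.csv"
    frame.to_csv(path, index=False, float_format="%.6g")
    written[name] = path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest dict.

    Writes ``scored_cohort.csv``, ``rejects.csv``, the report tables and
    ``manifest.json`` under ``config.out_dir``.  Deterministic for a fixed
    config and seed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        gen = default_config(**config.simulate)
        table = generate_cohort(gen, seed=config.seed)
        log.info("simulated cohort: %d rows", len(table))
    else:
        table = read_cohort(config.input_path, column_map=config.column_map)
        log.info(
            "read cohort: %d rows, %d rejected", len(table), len(table.rejects)
        )
    write_rejects(table, out_dir / "rejects.csv")

    df = prepare_scored_cohort(table)
    if config.missing_ldl == "complete_case":
        df = df[df["ldl_hdl_category"].notna()]
    df.to_csv(out_dir / "scored_cohort.csv", index=False, float_format="%.6g")

    written: dict[str, Path] = {"scored_cohort": out_dir / "scored_cohort.csv",
                                "rejects": out_dir / "rejects.csv"}
    if "render" in config.stages or "analyze" in config.stages:
        written.update(
            render_tables(
                df, out_dir, config.strata, config.seed, config.regression_covariates
            )
        )

    cfg_repr = {
        "seed": config.seed,
        "input_path": str(config.input_path) if config.input_path else None,
        "simulate": config.simulate,
        "stages": list(config.stages),
        "missing_ldl": config.missing_ldl,
        "strata": [list(s) for s in config.strata],
        "regression_covariates": list(config.regression_covariates),
    }
    manifest = {
        "package_version": __version__,
        "points_table_version": load_points_table().version,
        "config": cfg_repr,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_repr, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {k: _sha256(p) for k, p in sorted(written.items())},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
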