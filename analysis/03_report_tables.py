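"""Render the report tables from the scored cohort.

Produces the study-shaped tables under results/report/: population
characteristics by sex, mean ALLY by index category, index/ALLY means by
age band, high-ALLY prevalence by category, the age-stratified odds-ratio
table, AUCs with DeLong intervals, and Youden-optimal cut-offs, plus ROC
operating points per index and sex.

The stratified regression is run without the smoker covariate: under the
printed points table non-smokers cannot reach the 17-year cut-off, so the
smoker term is quasi-separated by construction (see docs/methods.md).

Run:  python analysis/03_report_tables.py [--seed 42]
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from heartage.pipeline import REGRESSION_COVARIATES, render_tables

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    scored = ROOT / "scratch" / "scored.csv"
    if not scored.exists():
        raise SystemExit("run analysis/02_score_and_index.py first")
    df = pd.read_csv(scored)

    out = ROOT / "results" / "report"
    strata = [(20, 30), (30, 40), (40, 50), (50, 60), (60, 70)]
    covs = [c for c in REGRESSION_COVARIATES if c != "smoker"]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        written = render_tables(df, out, strata, seed=seed, regression_covariates=covs)
    for w in caught:
        print(f"diagnostic: {w.message}")

    print(f"wrote {len(written)} tables to {out}")
    t7 = pd.read_csv(out / "table7_auc.csv")
    print("\nAUC of each index for predicting high ALLY heart age:")
    print(t7[["index", "sex", "auc_ci"]].to_string(index=False))
    t3 = pd.read_csv(out / "table3_ally_by_index.csv")
    tc = t3[t3["index"] == "tc_hdl"].pivot(index="category", columns="sex",
                                           values="mean_ally")
    print("\nmean ALLY by TC/HDL category (rises with category in both sexes):")
    print(tc.loc[["low", "moderate", "high"]].round(2).to_string())


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    main(ap.parse_args().seed)
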