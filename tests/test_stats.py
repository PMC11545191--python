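"""ROC/AUC/Youden, logistic IRLS, Hosmer–Lemeshow, bivariate tests.

Each computation is checked against an independent route: brute-force pair
enumeration for the AUC, an exhaustive threshold scan for Youden, the
statsmodels MLE for the logistic solver, a value frozen from R's pROC for
the DeLong interval, and hand-computed contingency statistics.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from heartage.simulate import default_config, generate_cohort, inject_known_effect
from heartage.stats import (
    SeparationError,
    auc_rank_oracle,
    bivariate_tables,
    build_design,
    fit_logistic,
    hosmer_lemeshow,
    roc_curve,
    stratified_analysis,
    youden_cutoff,
)


def _brute_force_auc(scores, labels):
    """All-pairs concordance, ties counted half (the AUC's definition)."""
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return ((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (
        pos.shape[0] * neg.shape[1]
    )


class TestRoc:
    def test_trapezoid_equals_all_pairs_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(10, 200))
            s = np.round(rng.normal(size=n), 1)  # ties on purpose
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            expected = _brute_force_auc(s, y)
            r = roc_curve(s, y)
            assert abs(r.auc - expected) < 1e-12
            assert abs(auc_rank_oracle(s, y) - expected) < 1e-12

    def test_perfect_separation(self):
        r = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert 2 < r.best_cutoff < 3
        assert r.youden_j == 1.0

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(12)
        s = rng.normal(size=10000)
        y = rng.integers(0, 2, 10000)
        assert abs(roc_curve(s, y).auc - 0.5) < 0.02

    def test_auc_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-s))).astype(int)
        base = roc_curve(s, y).auc
        for f in (np.exp, lambda x: x**3, np.arctan):
            assert abs(roc_curve(f(s), y).auc - base) < 1e-12

    def test_delong_interval_matches_proc_reference(self):
        # frozen from R pROC::ci.auc(..., method="delong") on this fixture
        score = np.array([0.1, 0.4, 0.35, 0.8, 0.45, 0.2, 0.7, 0.6, 0.15, 0.9, 0.5, 0.3])
        lab = np.array([0, 0, 1, 1, 0, 0, 1, 1, 0, 1, 1, 0])
        r = roc_curve(score, lab)
        assert r.auc == pytest.approx(0.944444444444, abs=1e-10)
        assert r.auc_ci[0] == pytest.approx(0.815607741061, abs=1e-9)
        assert r.auc_ci[1] == 1.0  # clipped at the upper bound

    def test_bootstrap_ci_close_to_delong(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=400) + np.repeat([0.0, 1.0], 200)
        y = np.repeat([0, 1], 200)
        d = roc_curve(s, y)
        b = roc_curve(s, y, ci_method="bootstrap", n_boot=500, seed=9)
        assert abs(d.auc_ci[0] - b.auc_ci[0]) < 0.03
        assert abs(d.auc_ci[1] - b.auc_ci[1]) < 0.03

    def test_youden_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            s = np.round(rng.normal(size=n), 1)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            r = roc_curve(s, y)
            cut, sens, spec, j = youden_cutoff(r)
            best = -2.0
            for t in r.thresholds:
                se = ((s >= t) & (y == 1)).sum() / (y == 1).sum()
                sp = ((s < t) & (y == 0)).sum() / (y == 0).sum()
                best = max(best, se + sp - 1.0)
            assert j == pytest.approx(best, abs=1e-12)
            assert j == pytest.approx(sens + spec - 1.0, abs=1e-12)

    def test_identical_scores_degenerate_to_zero_youden(self):
        r = roc_curve([2.0] * 10, [0, 1] * 5)
        assert r.youden_j == 0.0
        assert np.isinf(r.best_cutoff)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            roc_curve([1, 2, 3], [1, 1, 1])

    def test_sensitivity_specificity_monotone_in_threshold(self):
        rng = np.random.default_rng(23)
        s = rng.normal(size=500)
        y = rng.integers(0, 2, 500)
        r = roc_curve(s, y)
        order = np.argsort(r.thresholds)
        assert (np.diff(r.sensitivity[order]) <= 1e-12).all()
        assert (np.diff(r.specificity[order]) >= -1e-12).all()


class TestLogistic:
    def test_two_by_two_odds_ratio_closed_form(self):
        # exposed: 50% outcome, unexposed: 25% -> OR = (1)/(1/3) = 3 exactly
        x = np.r_[np.ones(200), np.zeros(200)]
        y = np.r_[np.ones(100), np.zeros(100), np.ones(50), np.zeros(150)]
        fit = fit_logistic(pd.DataFrame({"const": 1.0, "exposed": x}), y)
        assert np.exp(fit.coef[1]) == pytest.approx(3.0, abs=1e-8)

    def test_matches_statsmodels_mle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {
                "const": 1.0,
                "x": rng.normal(size=400),
                "z": rng.integers(0, 2, 400).astype(float),
            }
        )
        eta = -0.4 + 0.9 * X["x"] - 0.5 * X["z"]
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.abs(fit.coef - ref.params.to_numpy()).max() < 1e-8
        assert np.abs(fit.se - ref.bse.to_numpy()).max() < 1e-6
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"const": 1.0, "x": rng.integers(0, 2, 2000).astype(float)})
        y = rng.integers(0, 2, 2000)
        row = fit_logistic(X, y).odds_ratios().iloc[0]
        assert abs(row["coef"]) < 3 * row["se"]

    def test_complete_separation_raises_diagnostic(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        with pytest.raises(SeparationError):
            fit_logistic(pd.DataFrame({"const": 1.0, "x": x}), y)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"const": [1.0, 1.0]}), [1, 1])

    def test_design_reference_levels(self):
        df = pd.DataFrame(
            {"grade": ["a", "b", "c", "a"], "flag": [True, False, True, False]}
        )
        X = build_design(df, ["grade", "flag"], {"grade": "a", "flag": "False"})
        assert set(X.columns) == {"const", "grade[b]", "grade[c]", "flag[True]"}
        with pytest.raises(ValueError, match="reference"):
            build_design(df, ["grade"], {"grade": "z"})


class TestHosmerLemeshow:
    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="insufficient groups"):
            hosmer_lemeshow([0.5, 0.5], [0, 1], groups=2)

    def test_saturated_categorical_model_fits_perfectly(self):
        # four groups, saturated model: fitted probs equal group rates exactly
        rng = np.random.default_rng(6)
        levels = np.repeat(["a", "b", "c", "d"], 100)
        rates = np.repeat([0.2, 0.4, 0.6, 0.8], 100)
        y = (rng.random(400) < rates).astype(int)
        X = build_design(pd.DataFrame({"lvl": levels}), ["lvl"], {"lvl": "a"})
        fit = fit_logistic(X, y)
        stat, df, _ = hosmer_lemeshow(fit.fitted, y, groups=4)
        assert df == 2
        assert stat == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_group_merged_with_warning(self):
        p = np.r_[np.full(50, 1e-15), np.linspace(0.2, 0.8, 150)]
        y = (np.linspace(0, 1, 200) > 0.5).astype(int)
        with pytest.warns(UserWarning, match="merging"):
            hosmer_lemeshow(p, y, groups=10)


class TestStratified:
    def test_homogeneous_effect_agrees_across_strata(self):
        cfg = inject_known_effect(
            default_config(n_male=8000, n_female=8000), target_or=2.0
        )
        df = generate_cohort(cfg, seed=50).data
        fits = stratified_analysis(
            df, "injected_outcome", ["smoker"], {"smoker": "False"}
        )
        assert len(fits) == 5
        for fit in fits.values():
            row = fit.odds_ratios().iloc[0]
            assert abs(row["coef"] - np.log(2.0)) < 3 * row["se"]

    def test_constructed_increasing_effect_recovered_in_order(self):
        rng = np.random.default_rng(60)
        df = generate_cohort(default_config(n_male=15000, n_female=15000), seed=61).data
        band = np.clip(((df["age"] - 20) // 10).astype(int), 0, 4)
        log_or = np.log([1.0, 2.0, 4.0, 8.0, 16.0])[band]
        eta = -2.0 + log_or * df["smoker"].to_numpy(float)
        df["y"] = rng.random(len(df)) < 1 / (1 + np.exp(-eta))
        fits = stratified_analysis(df, "y", ["smoker"], {"smoker": "False"})
        ors = [f.odds_ratios().iloc[0]["or"] for f in fits.values()]
        assert (np.diff(ors) > 0).all()

    def test_single_class_stratum_skipped_with_warning(self):
        df = generate_cohort(default_config(n_male=300, n_female=300), seed=62).data
        df["y"] = df["smoker"]
        df.loc[df["age"] < 30, "y"] = False  # all-negative youngest stratum
        with pytest.warns(UserWarning, match="20-30"):
            fits = stratified_analysis(df, "y", ["physically_active"])
        assert "20-30" not in fits


class TestBivariate:
    def test_identical_groups_show_no_difference(self):
        base = np.linspace(0, 1, 50)
        df = pd.DataFrame(
            {"g": ["a"] * 50 + ["b"] * 50, "v": np.r_[base, base]}
        )
        rep = bivariate_tables(df, "g", continuous=["v"])
        assert rep.continuous.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert rep.continuous.loc[0, "p"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_by_two_chi_square(self):
        # table [[20,10],[10,20]]: chi2 = 60·(400−100)²/30⁴ = 6.6667 plain,
        # 5.4 with the continuity correction
        df = pd.DataFrame(
            {
                "g": ["x"] * 30 + ["y"] * 30,
                "c": ["yes"] * 20 + ["no"] * 10 + ["yes"] * 10 + ["no"] * 20,
            }
        )
        rep = bivariate_tables(df, "g", categorical=["c"])
        assert rep.categorical.loc[0, "statistic"] == pytest.approx(20 / 3, abs=1e-9)
        rep_cc = bivariate_tables(df, "g", categorical=["c"], continuity=True)
        assert rep_cc.categorical.loc[0, "statistic"] == pytest.approx(5.4, abs=1e-9)

    def test_sparse_table_falls_back_to_fisher(self):
        df = pd.DataFrame(
            {"g": ["x"] * 3 + ["y"] * 3, "c": ["a", "a", "a", "b", "b", "b"]}
        )
        rep = bivariate_tables(df, "g", categorical=["c"])
        assert (rep.categorical["test"] == "fisher").all()
        assert any("Fisher" in note for note in rep.notes)

    def test_nonbinary_grouping_rejected(self):
        df = pd.DataFrame({"g": ["a", "b", "c"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="binary"):
            bivariate_tables(df, "g", continuous=["v"])

    def test_welch_t_type_one_error_near_nominal(self):
        rng = np.random.default_rng(99)
        a = rng.normal(size=(2000, 30))
        b = rng.normal(size=(2000, 30))
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
        rate = (p < 0.05).mean()
        assert 0.03 <= rate <= 0.07
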