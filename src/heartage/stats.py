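"""Statistics stages: ROC/Youden cut-off discovery, logistic regression with
odds ratios and Hosmer–Lemeshow fit, and bivariate descriptive tables.

The ROC machinery (trapezoidal AUC, DeLong variance, Youden-maximizing
cut-off) and the logistic-regression solver (Newton/IRLS) are implemented
here directly; the bivariate stage delegates to scipy.stats for the Welch t,
chi-square and Fisher exact tests.

Conventions
-----------
* ROC orientation: a higher score predicts the positive class; thresholds
  sit at midpoints between distinct observed scores, with ∓∞ sentinels.
* Youden ties break toward the smallest threshold.
* Odds ratios are ``exp(coef)`` with Wald 95% CIs ``exp(coef ± 1.96·SE)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RocResult",
    "LogisticFit",
    "BivariateReport",
    "roc_curve",
    "youden_cutoff",
    "auc_rank_oracle",
    "build_design",
    "fit_logistic",
    "hosmer_lemeshow",
    "stratified_analysis",
    "bivariate_tables",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# --------------------------------------------------------------------------
# ROC / AUC / Youden
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    """Operating points and summary of one ROC analysis."""

    thresholds: np.ndarray      # descending sentinel +inf ... -inf
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    best_cutoff: float
    best_sensitivity: float
    best_specificity: float
    youden_j: float
    n_pos: int = 0
    n_neg: int = 0


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate ROC: only one class present")
    return y


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from positive/negative score samples."""
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n            # structural components, positives
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m      # negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_curve(
    scores,
    labels,
    ci_method: str = "delong",
    n_boot: int = 1000,
    seed: int | None = None,
) -> RocResult:
    """Full ROC analysis of a score against a binary outcome.

    Thresholds are the midpoints between consecutive distinct scores plus
    ±∞ sentinels; a score at or above the threshold is called positive.  The
    AUC is the trapezoidal area (equal to the tie-corrected rank statistic);
    its 95% CI uses the DeLong variance estimator, or a seeded bootstrap when
    ``ci_method='bootstrap'``.  The reported cut-off maximizes the Youden
    index J = sensitivity + specificity − 1, ties toward the smaller
    threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")

    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    # sort descending once; thresholds between distinct scores via cumsums
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    ends = np.flatnonzero(np.diff(s_sorted) != 0)      # last index of each group
    ends = np.append(ends, len(s_sorted) - 1)
    uniq_desc = s_sorted[ends]
    mids = (uniq_desc[:-1] + uniq_desc[1:]) / 2.0
    thresholds = np.concatenate([[np.inf], mids, [-np.inf]])
    # predicted positive iff score >= threshold
    tp = np.concatenate([[0.0], tp_cum[ends]])
    fp = np.concatenate([[0.0], fp_cum[ends]])
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg

    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    if ci_method == "delong":
        _, var = _delong_variance(s[y == 1], s[y == 0])
        half = Z95 * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bp = s[rng.choice(idx_pos, n_pos)]
            bn = s[rng.choice(idx_neg, n_neg)]
            reps[b] = auc_rank_oracle(
                np.concatenate([bp, bn]),
                np.concatenate([np.ones(n_pos), np.zeros(n_neg)]),
            )
        ci = tuple(np.quantile(reps, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")

    j = sens + spec - 1.0
    # argmax with ties toward the smallest threshold: scan ascending thresholds
    order = np.argsort(thresholds, kind="stable")
    best_pos = order[np.argmax(j[order])]
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=ci,
        best_cutoff=float(thresholds[best_pos]),
        best_sensitivity=float(sens[best_pos]),
        best_specificity=float(spec[best_pos]),
        youden_j=float(j[best_pos]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def youden_cutoff(roc: RocResult) -> tuple[float, float, float, float]:
    """(cutoff, sensitivity, specificity, J) at the Youden maximizer."""
    return roc.best_cutoff, roc.best_sensitivity, roc.best_specificity, roc.youden_j


def auc_rank_oracle(scores, labels) -> float:
    """AUC as the all-pairs concordance statistic (ties count half).

    Uses midranks, equivalent to explicit pair enumeration; serves as the
    rank-statistic route to the same quantity the trapezoid computes.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    m = int(y.sum())
    n = len(y) - m
    ranks = _midrank(s)
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


# --------------------------------------------------------------------------
# Logistic regression (Newton / IRLS)
# --------------------------------------------------------------------------

class SeparationError(RuntimeError):
    """The likelihood is unbounded (complete or quasi-complete separation)."""


@dataclass
class LogisticFit:
    """A fitted binary logistic model."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    fitted: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    n: int

    def odds_ratios(self) -> pd.DataFrame:
        """OR with Wald 95% CI per non-intercept term."""
        rows = []
        for t, b, s in zip(self.terms, self.coef, self.se):
            if t == "const":
                continue
            rows.append(
                {
                    "term": t,
                    "or": float(np.exp(b)),
                    "ci_low": float(np.exp(b - Z95 * s)),
                    "ci_high": float(np.exp(b + Z95 * s)),
                    "coef": float(b),
                    "se": float(s),
                }
            )
        return pd.DataFrame(rows)


def build_design(
    df: pd.DataFrame,
    covariates: list[str],
    references: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Expand covariates into a design matrix with an intercept.

    Categorical (object/bool/category) columns are dummy-coded against the
    declared reference level (defaulting to the most frequent level); numeric
    columns pass through.  Dummy columns are named ``col[level]`` so the
    reference, which carries OR 1 by definition, is implicit.
    """
    references = references or {}
    parts = {"const": np.ones(len(df))}
    for c in covariates:
        col = df[c]
        if col.dtype == bool or col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            levels = {str(lv) for lv in pd.unique(col) if not pd.isna(lv)}
            ref = str(references.get(c, col.mode().iloc[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found in {c!r}")
            for lv in sorted(levels - {ref}):
                parts[f"{c}[{lv}]"] = (col.astype(str) == lv).to_numpy(float)
        else:
            parts[c] = col.to_numpy(float)
    return pd.DataFrame(parts, index=df.index)


def fit_logistic(
    design: pd.DataFrame,
    outcome,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Convergence when the maximum absolute score (gradient) drops below
    ``tol``; raises :class:`SeparationError` on diverging coefficients and
    :class:`RuntimeError` on non-convergence rather than returning a silent
    result.
    """
    X = design.to_numpy(float)
    y = np.asarray(outcome).astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        xtwx = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (separation or collinearity)"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError(
                "coefficients diverging; data are (quasi-)separated"
            )
    if not converged:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")

    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    eps = 1e-12
    loglik = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return LogisticFit(
        terms=list(design.columns),
        coef=beta,
        se=np.sqrt(np.diag(cov)),
        fitted=p,
        converged=converged,
        n_iter=it,
        loglik=loglik,
        n=n,
    )


def hosmer_lemeshow(
    fitted_probs,
    outcome,
    groups: int = 10,
) -> tuple[float, int, float]:
    """Hosmer–Lemeshow goodness-of-fit over predicted-risk groups.

    Groups by deciles of the fitted probabilities (``groups`` of them);
    the statistic is Σ (O−E)² / (E·(1−E/n_g)) over groups, df = groups − 2,
    p from the chi-square upper tail.  Groups whose expected count is
    degenerate are merged into a neighbour (logged via warning).
    """
    if groups <= 2:
        raise ValueError("insufficient groups: df = groups - 2 must be positive")
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(outcome).astype(float)
    qs = np.quantile(p, np.linspace(0, 1, groups + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    edges = np.unique(qs)
    bins = np.digitize(p, edges[1:-1], right=True)

    obs, exp, ns = [], [], []
    for b in np.unique(bins):
        m = bins == b
        obs.append(y[m].sum())
        exp.append(p[m].sum())
        ns.append(m.sum())
    obs, exp, ns = map(np.asarray, (obs, exp, ns))

    # merge groups whose expected count (either side) is ~0
    while len(ns) > 3:
        bad = np.flatnonzero((exp < 1e-9) | (ns - exp < 1e-9))
        if len(bad) == 0:
            break
        i = bad[0]
        j = i - 1 if i > 0 else i + 1
        warnings.warn("merging a degenerate Hosmer-Lemeshow group", stacklevel=2)
        obs[j] += obs[i]
        exp[j] += exp[i]
        ns[j] += ns[i]
        obs, exp, ns = np.delete(obs, i), np.delete(exp, i), np.delete(ns, i)

    g = len(ns)
    if g <= 2:
        raise ValueError("insufficient groups after merging")
    denom = exp * (1.0 - exp / ns)
    denom = np.where(denom <= 0, np.nan, denom)
    stat = float(np.nansum((obs - exp) ** 2 / denom))
    df = g - 2
    pval = float(sps.chi2.sf(stat, df))
    return stat, df, pval


def stratified_analysis(
    df: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    references: dict[str, str] | None = None,
    strata: list[tuple[float, float]] | None = None,
    age_col: str = "age",
) -> dict[str, LogisticFit]:
    """Independent logistic fits per age band, as in age-stratified OR tables.

    ``strata`` are half-open [lo, hi) age bands (default: the five decade
    bands 20–70).  Bands that are empty or single-class in the outcome are
    skipped with a warning, never fit silently.
    """
    strata = strata or [(20, 30), (30, 40), (40, 50), (50, 60), (60, 70)]
    out: dict[str, LogisticFit] = {}
    for lo, hi in strata:
        label = f"{int(lo)}-{int(hi)}"
        sub = df[(df[age_col] >= lo) & (df[age_col] < hi)]
        y = sub[outcome].astype(int) if len(sub) else pd.Series(dtype=int)
        if len(sub) == 0 or y.nunique() < 2:
            warnings.warn(f"stratum {label} skipped: empty or single-class", stacklevel=2)
            continue
        X = build_design(sub, covariates, references)
        try:
            out[label] = fit_logistic(X, y)
        except (SeparationError, RuntimeError) as exc:
            warnings.warn(f"stratum {label} skipped: {exc}", stacklevel=2)
    return out


# --------------------------------------------------------------------------
# Bivariate descriptives
# --------------------------------------------------------------------------

@dataclass
class BivariateReport:
    """Group-wise descriptives with test p-values."""

    continuous: pd.DataFrame   # field, mean/SD per group, t, p
    categorical: pd.DataFrame  # field, level, n/% per group, statistic, p, test
    group_labels: tuple = ()
    notes: list[str] = field(default_factory=list)


def _chi2_or_fisher(table: np.ndarray, continuity: bool = False):
    """Chi-square test with the Fisher-exact fallback for sparse 2×2 tables."""
    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any() and table.shape == (2, 2):
        _, p = sps.fisher_exact(table)
        return np.nan, p, "fisher"
    stat, p, _, _ = sps.chi2_contingency(table, correction=continuity)
    return stat, p, "chi2"


def bivariate_tables(
    df: pd.DataFrame,
    group: str,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    continuity: bool = False,
) -> BivariateReport:
    """Mean-comparison (Welch t) and association (chi²/Fisher) tables.

    ``group`` must be binary.  Continuous fields get per-group mean (SD) and
    a Welch two-sample t-test; categorical fields get per-group counts and
    percentages with a chi-square test, falling back to Fisher's exact test
    for 2×2 tables with any expected cell below 5 (noted in ``notes``).
    """
    levels = [lv for lv in pd.unique(df[group]) if not pd.isna(lv)]
    if len(levels) != 2:
        raise ValueError(f"grouping variable {group!r} must be binary")
    g0, g1 = sorted(map(str, levels))
    a = df[df[group].astype(str) == g0]
    b = df[df[group].astype(str) == g1]

    notes: list[str] = []
    cont_rows = []
    for fld in continuous or []:
        x, yv = a[fld].dropna(), b[fld].dropna()
        t, p = sps.ttest_ind(x, yv, equal_var=False)
        cont_rows.append(
            {
                "field": fld,
                f"mean_{g0}": x.mean(), f"sd_{g0}": x.std(ddof=1),
                f"mean_{g1}": yv.mean(), f"sd_{g1}": yv.std(ddof=1),
                "t": float(t), "p": float(p),
            }
        )

    cat_rows = []
    for fld in categorical or []:
        tab = pd.crosstab(df[fld], df[group].astype(str))
        stat, p, which = _chi2_or_fisher(tab.to_numpy(), continuity)
        if which == "fisher":
            notes.append(f"{fld}: expected cell < 5, Fisher exact used")
        for lv in tab.index:
            cat_rows.append(
                {
                    "field": fld, "level": lv,
                    f"n_{g0}": int(tab.loc[lv, g0]),
                    f"pct_{g0}": 100.0 * tab.loc[lv, g0] / tab[g0].sum(),
                    f"n_{g1}": int(tab.loc[lv, g1]),
                    f"pct_{g1}": 100.0 * tab.loc[lv, g1] / tab[g1].sum(),
                    "statistic": stat, "p": float(p), "test": which,
                }
            )
    return BivariateReport(
        continuous=pd.DataFrame(cont_rows),
        categorical=pd.DataFrame(cat_rows),
        group_labels=(g0, g1),
        notes=notes,
    )
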