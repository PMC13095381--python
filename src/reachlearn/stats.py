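"""Learning Index and the longitudinal statistical comparison scheme.

The statistical plan mirrors standard practice for this task:

* time courses (metric × day × group) go to a repeated-measures two-way
  ANOVA (subject as the repeated unit, Greenhouse–Geisser correction) when
  the subject × day table is complete, and to a linear mixed model with a
  per-subject random intercept whenever any cell is missing — e.g. a mouse
  that made no reach attempts on a day has no per-reach metric there;
* Day 1 vs Day 8 paired comparisons use a paired t test or a Wilcoxon
  matched-pairs signed-rank test, gated by a Shapiro–Wilk normality test on
  the paired differences;
* unpaired group comparisons (Learning Indices) use Welch's t test.

Branch selection is a pure function of the data and is recorded in every
result for auditability. All tests are two-sided; no multiple-testing
correction is applied across metrics.

The Learning Index of a metric is the Day 1 vs Day 8 difference for one
animal, signed so that positive always means improvement: Day1 − Day8 for
metrics that decrease with learning (misses, vain %, reach distance, ΔY,
ΔX), Day8 − Day1 for metrics that increase (success rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

ALPHA_NORMALITY = 0.05

#: metric name -> orientation ("increase" if larger values mean better
#: performance, "decrease" otherwise)
ORIENTATION: dict[str, str] = {
    "success_by_trial_pct": "increase",
    "success_by_reach_pct": "increase",
    "first_reach_success_pct": "increase",
    "complete_miss_pct": "decrease",
    "contact_miss_pct": "decrease",
    "vain_pct": "decrease",
    "path_length_px": "decrease",
    "delta_y_px": "decrease",
    "delta_x_px": "decrease",
}


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    test: str  # which test actually ran (the branch taken)
    statistic: float
    df: float | tuple[float, float] | None
    pvalue: float
    n: int | tuple[int, int]
    direction: float = 0.0  # sign of the effect (mean difference)

    def __post_init__(self) -> None:
        if not (np.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0,1]")


# ---------------------------------------------------------------------------
# Learning Index


def learning_index(
    values_by_day: "pd.Series | dict[int, float]",
    orientation: str,
    first_day: int = 1,
    last_day: int = 8,
) -> float:
    """Per-animal Learning Index; NaN if either endpoint day is missing."""
    if orientation not in ("increase", "decrease"):
        raise ValueError(f"unknown orientation {orientation!r}")
    s = pd.Series(values_by_day)
    v1 = s.get(first_day, np.nan)
    v8 = s.get(last_day, np.nan)
    if pd.isna(v1) or pd.isna(v8):
        return np.nan
    return float(v8 - v1) if orientation == "increase" else float(v1 - v8)


def learning_indices(
    table: pd.DataFrame,
    metric: str,
    orientation: str | None = None,
    first_day: int = 1,
    last_day: int | None = None,
) -> pd.DataFrame:
    """Learning Index per subject from a long (subject, day, metric) table.

    Carries through any grouping columns (group, genotype, condition, sex)
    constant within subject.
    """
    if orientation is None:
        orientation = ORIENTATION.get(metric)
        if orientation is None:
            raise ValueError(f"no registered orientation for metric {metric!r}")
    last_day = int(table["day"].max()) if last_day is None else last_day
    meta_cols = [c for c in ("group", "genotype", "condition", "sex") if c in table.columns]
    rows = []
    for subject, sub in table.groupby("subject"):
        by_day = sub.set_index("day")[metric]
        li = learning_index(by_day, orientation, first_day, last_day)
        row = {"subject": subject, "metric": metric, "learning_index": li}
        for c in meta_cols:
            row[c] = sub[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired and unpaired comparisons


def day1_vs_day8_test(
    values_day1,
    values_day8,
    alpha_normality: float = ALPHA_NORMALITY,
) -> TestResult:
    """Paired Day 1 vs Day 8 comparison with a Shapiro–Wilk normality gate.

    Differences passing the normality test go to a paired t test, otherwise
    to a Wilcoxon matched-pairs signed-rank test (two-sided).
    """
    a = np.asarray(values_day1, dtype=float)
    b = np.asarray(values_day8, dtype=float)
    if a.shape != b.shape:
        raise ValueError("day-1 and day-8 vectors must be paired (equal length)")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 3:
        raise InsufficientDataError(f"only {n} complete pairs; need >= 3")
    diff = b - a
    if np.all(diff == diff[0]):
        if diff[0] == 0.0:  # identical vectors: exact null
            return TestResult("paired_t", 0.0, n - 1, 1.0, n, 0.0)
        normal_p = 1.0  # constant nonzero shift: t test is exact
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal_p = float(sps.shapiro(diff).pvalue)
    direction = float(np.sign(np.mean(diff)))
    if normal_p >= alpha_normality:
        res = sps.ttest_rel(b, a)
        return TestResult("paired_t", float(res.statistic), n - 1, float(res.pvalue), n, direction)
    res = sps.wilcoxon(b, a, zero_method="wilcox", mode="auto")
    return TestResult("wilcoxon", float(res.statistic), None, float(res.pvalue), n, direction)


def group_li_test(li_group_a, li_group_b) -> TestResult:
    """Welch's unequal-variance two-sample t test (two-sided) on Learning Indices."""
    a = np.asarray(li_group_a, dtype=float)
    b = np.asarray(li_group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError(
            f"need >= 3 non-missing indices per group, got {len(a)} and {len(b)}"
        )
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate zero-variance groups: exact equality fast path
        equal = a[0] == b[0]
        return TestResult(
            "welch_t", 0.0 if equal else np.inf, len(a) + len(b) - 2,
            1.0 if equal else 0.0, (len(a), len(b)), float(np.sign(a[0] - b[0])),
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    # Welch–Satterthwaite degrees of freedom
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return TestResult(
        "welch_t", float(res.statistic), float(df), float(res.pvalue),
        (len(a), len(b)), float(np.sign(a.mean() - b.mean())),
    )


# ---------------------------------------------------------------------------
# longitudinal models


@dataclass(frozen=True)
class LongitudinalResult:
    model: str  # "rm_anova" | "mixed"
    group_effect: TestResult
    day_effect: TestResult
    interaction: TestResult
    n_subjects: int
    n_missing_cells: int


def _validate_design(table: pd.DataFrame, group_col: str) -> None:
    levels = table[group_col].dropna().unique()
    if len(levels) < 2:
        raise InsufficientDataError(f"factor {group_col!r} needs >= 2 levels, got {list(levels)}")
    per_level = table.groupby(group_col)["subject"].nunique()
    if (per_level < 3).any():
        raise InsufficientDataError(f"every {group_col!r} level needs >= 3 subjects:\n{per_level}")
    if table["day"].nunique() < 2:
        raise InsufficientDataError("need >= 2 days")


def longitudinal_model(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "genotype",
) -> LongitudinalResult:
    """Group × day analysis of a learning curve.

    With a complete subject × day table this is a two-way repeated-measures
    ANOVA (between factor ``group_col``, within factor day, Greenhouse–
    Geisser-corrected within dfs); with any missing value it is a linear
    mixed model with a per-subject random intercept and sum-coded fixed
    effects group, day and group × day, tested by Wald chi-square. Any column
    (e.g. ``sex``) can serve as the grouping factor.
    """
    df = table[["subject", group_col, "day", metric]].copy()
    _validate_design(df, group_col)
    pivot = df.pivot_table(index="subject", columns="day", values=metric, dropna=False)
    all_days = sorted(df["day"].unique())
    n_missing = int(pivot.reindex(columns=all_days).isna().sum().sum())
    if n_missing == 0:
        return _rm_anova(df, metric, group_col, pivot)
    return _mixed_model(df, metric, group_col, n_missing)


def _rm_anova(df, metric, group_col, pivot) -> LongitudinalResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=df, dv=metric, within="day", subject="subject",
            between=group_col, correction=True,
        ).set_index("Source")
    eps = float(aov.loc["day"].get("eps", 1.0))
    if not np.isfinite(eps):
        eps = 1.0

    def effect(source: str, correct: bool) -> TestResult:
        row = aov.loc[source]
        if "F" not in row.index or pd.isna(row["F"]):
            # zero-variance data: no effect by construction (exact null)
            return TestResult("rm_anova_F", 0.0,
                              (float(row["DF1"]), float(row["DF2"])), 1.0, pivot.shape[0])
        F, df1, df2 = float(row["F"]), float(row["DF1"]), float(row["DF2"])
        p = float(row["p_unc"])
        if correct:
            # GG correction: shrink both dfs by the within-factor epsilon
            p_gg = row.get("p_GG_corr", np.nan)
            if pd.notna(p_gg):
                p, df1, df2 = float(p_gg), eps * df1, eps * df2
            elif eps < 1.0:
                df1, df2 = eps * df1, eps * df2
                p = float(sps.f.sf(F, df1, df2))
        return TestResult("rm_anova_F", F, (df1, df2), p, pivot.shape[0])

    return LongitudinalResult(
        model="rm_anova",
        group_effect=effect(group_col, correct=False),
        day_effect=effect("day", correct=True),
        interaction=effect("Interaction", correct=True),
        n_subjects=pivot.shape[0],
        n_missing_cells=0,
    )


def _mixed_model(df, metric, group_col, n_missing) -> LongitudinalResult:
    import statsmodels.formula.api as smf

    data = df.dropna(subset=[metric]).copy()
    data["day"] = data["day"].astype(int)
    formula = f"{metric} ~ C({group_col}, Sum) * C(day, Sum)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(formula, data, groups=data["subject"]).fit(reml=True)
    names = list(fit.fe_params.index)

    def wald(cols: list[int]) -> TestResult:
        L = np.zeros((len(cols), len(fit.params)))
        for r, c in enumerate(cols):
            L[r, c] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = fit.wald_test(L, scalar=False)
        stat = float(np.squeeze(wt.statistic))
        dof = float(wt.df_denom)
        return TestResult("mixed_wald_chi2", stat, dof, float(np.squeeze(wt.pvalue)),
                          data["subject"].nunique())

    g_cols = [i for i, nm in enumerate(names) if group_col in nm and ":" not in nm]
    d_cols = [i for i, nm in enumerate(names) if nm.startswith("C(day") and ":" not in nm]
    i_cols = [i for i, nm in enumerate(names) if ":" in nm]
    return LongitudinalResult(
        model="mixed",
        group_effect=wald(g_cols),
        day_effect=wald(d_cols),
        interaction=wald(i_cols),
        n_subjects=data["subject"].nunique(),
        n_missing_cells=n_missing,
    )


def longitudinal_report(
    table: pd.DataFrame,
    metrics: list[str],
    group_col: str = "genotype",
) -> pd.DataFrame:
    """Tabular report over several metrics (one row per effect per metric)."""
    rows = []
    for metric in metrics:
        try:
            res = longitudinal_model(table, metric, group_col)
        except InsufficientDataError as exc:
            rows.append({"metric": metric, "comparison": f"{group_col} x day",
                         "model": "skipped", "note": str(exc)})
            continue
        for name, tr in (
            (group_col, res.group_effect), ("day", res.day_effect),
            ("interaction", res.interaction),
        ):
            rows.append({
                "metric": metric, "comparison": f"{group_col} x day", "effect": name,
                "model": res.model, "test": tr.test, "statistic": tr.statistic,
                "df": str(tr.df), "p": tr.pvalue, "n_subjects": res.n_subjects,
                "n_missing_cells": res.n_missing_cells,
            })
    return pd.DataFrame(rows)
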