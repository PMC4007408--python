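"""Cohort survival and the study's inferential statistics.

Group comparisons use the classical toolkit: unpaired pooled-variance
(Student) t-tests for two groups, one-way ANOVA for several, and the
Newman–Keuls stepwise studentized-range post-test for pairwise comparisons
after a significant ANOVA.  A config switch selects Welch's t-test where
unequal variances are a concern, but the pooled test is the default.

Survival between 2 and 3 dpf is the 3-dpf cell count (including cells that
newly express the reporter during the interval) as a percentage of the 2-dpf
count, and may therefore exceed 100%.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field  # field: pairwise excluded from comparisons

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SurvivalResult",
    "TestResult",
    "survival_percent",
    "ttest_unpaired",
    "anova_oneway",
    "newman_keuls",
    "studentized_range_quantile",
]


@dataclass(frozen=True)
class SurvivalResult:
    condition: str
    pct_survival: float  # may exceed 100
    n_t1: int
    n_t2: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def survival_percent(table: pd.DataFrame, condition: str | None = None) -> SurvivalResult:
    """Percent survival from a cohort table.

    ``table`` needs boolean columns ``present_at_t1``, ``present_at_t2`` and
    ``newly_appeared`` (newly appeared cells are counted at t2 only).  The
    percentage is 100 × (count at t2) / (count at t1).
    """
    df = table
    if condition is not None:
        df = df[df["condition"] == condition]
    if df["newly_appeared"].any() and (df["newly_appeared"] & df["present_at_t1"]).any():
        raise ValueError("newly_appeared cells cannot be present at t1")
    n_t1 = int(df["present_at_t1"].sum())
    if n_t1 == 0:
        raise ValueError("no cells present at the first timepoint")
    n_t2 = int(df["present_at_t2"].sum())
    name = condition if condition is not None else (
        df["condition"].iloc[0] if "condition" in df and df["condition"].nunique() == 1 else "all"
    )
    return SurvivalResult(str(name), 100.0 * n_t2 / n_t1, n_t1, n_t2)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    method: str
    pairwise: pd.DataFrame | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "method": self.method,
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


def ttest_unpaired(a, b, equal_var: bool = True) -> TestResult:
    """Two-sample unpaired t-test (pooled variance by default), two-sided.

    When both samples have zero variance and equal means the test is
    degenerate and p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, (a.size + b.size - 2,), 1.0, "t-test (pooled)")
        return TestResult(math.inf, (a.size + b.size - 2,), 0.0, "t-test (pooled)")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    method = "t-test (pooled)" if equal_var else "t-test (Welch)"
    return TestResult(float(res.statistic), (float(res.df),), float(res.pvalue), method)


def anova_oneway(groups: list) -> TestResult:
    """One-way ANOVA: F with (k−1, N−k) degrees of freedom."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    if all(g.std(ddof=1) == 0 for g in groups) and len({float(g.mean()) for g in groups}) == 1:
        return TestResult(0.0, (k - 1, n_total - k), 1.0, "one-way ANOVA")
    f, p = sps.f_oneway(*groups)
    return TestResult(float(f), (k - 1, n_total - k), float(p), "one-way ANOVA")


def studentized_range_quantile(alpha: float, n_means: int, df: float) -> float:
    """Upper-α quantile of the studentized range q(α; k, ν), computed numerically."""
    return float(sps.studentized_range.isf(alpha, n_means, df))


def newman_keuls(groups: list, alpha: float = 0.05, labels: list[str] | None = None) -> TestResult:
    """Newman–Keuls stepwise post-test on the studentized range.

    Groups are ordered by mean; for the pair (i, j) spanning r ordered means
    the statistic is q = (mean_i − mean_j) / sqrt(MSE/2 · (1/n_i + 1/n_j))
    with the critical value q(α; r, df_error).  Testing proceeds from the
    widest stretch inward; every comparison interior to a non-significant
    stretch is declared non-significant without testing (the stepwise
    protection that distinguishes this procedure from Tukey's HSD).

    Returns the overall ANOVA result with a pairwise table attached
    (columns: group_a, group_b, mean_diff, q, stretch, p_value, significant).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    anova = anova_oneway(groups)
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    n = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df_error = int(sum(n) - k)
    mse = sum(float(((g - g.mean()) ** 2).sum()) for g in groups) / df_error
    order = np.argsort(means)  # ascending

    results: dict[tuple[int, int], dict] = {}
    blocked: set[tuple[int, int]] = set()
    # stretches from widest to narrowest
    for stretch in range(k, 1, -1):
        for lo in range(0, k - stretch + 1):
            hi = lo + stretch - 1
            i, j = int(order[hi]), int(order[lo])  # larger mean, smaller mean
            key = (min(i, j), max(i, j))
            diff = float(means[i] - means[j])
            if mse > 0:
                q = diff / math.sqrt(mse / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
                p = float(sps.studentized_range.sf(q, stretch, df_error)) if q > 0 else 1.0
            else:
                q = math.inf if diff > 0 else 0.0
                p = 0.0 if diff > 0 else 1.0
            if key in blocked:
                results[key] = {"q": q, "stretch": stretch, "p": p, "sig": False, "diff": diff}
                continue
            sig = p < alpha
            results[key] = {"q": q, "stretch": stretch, "p": p, "sig": sig, "diff": diff}
            if not sig:
                # block all comparisons interior to this stretch
                for a in range(lo, hi + 1):
                    for b in range(a + 1, hi + 1):
                        kk = (min(int(order[a]), int(order[b])), max(int(order[a]), int(order[b])))
                        if kk != key and kk not in results:
                            blocked.add(kk)

    rows = []
    for (i, j) in itertools.combinations(range(k), 2):
        r = results[(i, j)]
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": means[i] - means[j],
                "q": r["q"],
                "stretch": r["stretch"],
                "p_value": r["p"],
                "significant": r["sig"],
            }
        )
    pairwise = pd.DataFrame(rows)
    return TestResult(
        anova.statistic, anova.df, anova.p_value, "one-way ANOVA + Newman-Keuls", pairwise
    )
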