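"""Summary statistics and the two-group test-selection decision tree.

Per-group summaries are mean ± SEM (SEM = sd/sqrt(n), sample sd with n-1
denominator) with a two-sided 95% confidence interval built from the
Student-t quantile at n-1 degrees of freedom.

Two-group comparisons follow a fixed decision tree: Shapiro-Wilk normality
on each group (alpha = 0.05); if both pass, an F-test of variances selects
the pooled unpaired t-test (equal variances) or Welch's t-test (unequal);
if either group is non-normal, the two-sided Mann-Whitney U test is used.
Differences are significant at p <= 0.05.  No multiple-testing correction
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "TestKind",
    "summarize",
    "confidence_interval",
    "variance_f_test",
    "compare",
]


class TestKind(str, Enum):
    UNPAIRED_T = "unpaired_t"
    WELCH_T = "welch_t"
    MANN_WHITNEY = "mann_whitney"


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ComparisonResult:
    test_used: TestKind
    p_value: float
    mean_difference: float
    significant: bool
    normality_p_a: float
    normality_p_b: float
    variance_test_p: float | None  # None when the F-test branch was not reached


def confidence_interval(
    mean: float, sem: float, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Two-sided Student-t CI, mean ± t(1-alpha/2, n-1)·sem."""
    if n < 2:
        raise ValueError("CI needs n >= 2")
    t = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return mean - t * sem, mean + t * sem


def summarize(values, confidence: float = 0.95) -> GroupSummary:
    """Mean ± SEM and Student-t confidence interval of a sample."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("summarize needs a 1-D sample with n >= 2")
    n = int(x.size)
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(n))
    lo, hi = confidence_interval(mean, sem, n, confidence)
    return GroupSummary(n=n, mean=mean, sem=sem, ci_low=lo, ci_high=hi)


def variance_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test p-value for equality of two normal variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va <= 0 or vb <= 0:
        return 1.0
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p_one = stats.f.sf(f, dfa, dfb) if f >= 1 else stats.f.cdf(f, dfa, dfb)
    return float(min(1.0, 2.0 * p_one))


def compare(group_a, group_b, alpha: float = 0.05) -> ComparisonResult:
    """Two-group comparison following the Shapiro → F → t/Welch/U tree."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("compare needs n >= 3 in each group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("degenerate data: both groups are constant")
    p_norm_a = float(stats.shapiro(a).pvalue)
    p_norm_b = float(stats.shapiro(b).pvalue)
    variance_p: float | None = None
    if p_norm_a > alpha and p_norm_b > alpha:
        variance_p = variance_f_test(a, b)
        if variance_p > alpha:
            kind = TestKind.UNPAIRED_T
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        else:
            kind = TestKind.WELCH_T
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        kind = TestKind.MANN_WHITNEY
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return ComparisonResult(
        test_used=kind,
        p_value=p,
        mean_difference=float(a.mean() - b.mean()),
        significant=bool(p <= alpha),
        normality_p_a=p_norm_a,
        normality_p_b=p_norm_b,
        variance_test_p=variance_p,
    )
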