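"""Statistical protocol shared by all quantification stages.

Normality is checked with the Shapiro-Wilk W test; two groups are
compared with an unpaired two-tailed Welch t-test (unequal-variance,
Welch-Satterthwaite degrees of freedom); three or more groups with
one-way ANOVA followed by Tukey's HSD multiple comparisons.  The
working significance level is 0.05 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "AnovaTable", "TukeyPair", "shapiro_wilk",
           "welch_ttest", "anova_tukey", "p_to_stars", "ConstantSampleError",
           "DegenerateTestWarning"]


class ConstantSampleError(ValueError):
    """All values identical: the test statistic is undefined."""


class DegenerateTestWarning(UserWarning):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    df: float = float("nan")
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class TukeyPair:
    group_i: int
    group_j: int
    mean_difference: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class AnovaTable:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p_value: float
    tukey: tuple[TukeyPair, ...]
    alpha: float = 0.05

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def shapiro_wilk(x: Sequence[float], alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk W test of normality (n >= 3, non-constant sample)."""
    arr = np.asarray(x, dtype=np.float64)
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(arr) == 0:
        raise ConstantSampleError("constant sample: W undefined")
    w, p = sps.shapiro(arr)
    return TestResult(statistic=float(w), p_value=float(p),
                      test_name="shapiro_wilk", alpha=alpha)


def welch_ttest(a: Sequence[float], b: Sequence[float],
                two_tailed: bool = True, alpha: float = 0.05) -> TestResult:
    """Unpaired Welch t-test.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom.  When both samples have
    zero variance and equal means the statistic is undefined; p is
    reported as 1 with a warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both samples with equal means: "
                          "t undefined, p = 1", DegenerateTestWarning, stacklevel=2)
            return TestResult(statistic=float("nan"), p_value=1.0,
                              test_name="welch_ttest", df=float("nan"), alpha=alpha)
        warnings.warn("zero variance in both samples with different means: "
                      "t infinite, p = 0", DegenerateTestWarning, stacklevel=2)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TestResult(statistic=sign * float("inf"), p_value=0.0,
                          test_name="welch_ttest", df=float("nan"), alpha=alpha)
    alternative = "two-sided" if two_tailed else "greater"
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      test_name="welch_ttest", df=float(res.df), alpha=alpha)


def anova_tukey(groups: Sequence[Sequence[float]],
                alpha: float = 0.05) -> AnovaTable | TestResult:
    """One-way ANOVA with Tukey HSD post-hoc on all pairs.

    With fewer than 3 groups the comparison is routed to
    :func:`welch_ttest` (with a notice), matching the protocol's
    two-group rule.
    """
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(g.size < 2 for g in arrs):
        raise ValueError("each group needs at least 2 observations")
    if len(arrs) < 3:
        if len(arrs) < 2:
            raise ValueError("need at least 2 groups")
        warnings.warn("fewer than 3 groups: using Welch t-test",
                      DegenerateTestWarning, stacklevel=2)
        return welch_ttest(arrs[0], arrs[1], alpha=alpha)

    pooled = np.concatenate(arrs)
    grand = pooled.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in arrs))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrs))
    df_between = len(arrs) - 1
    df_within = pooled.size - len(arrs)
    if ss_within == 0:
        f_stat = 0.0 if ss_between == 0 else float("inf")
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(f_stat, df_between, df_within))

    hsd = sps.tukey_hsd(*arrs)
    pairs = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            p_adj = float(hsd.pvalue[i, j])
            pairs.append(TukeyPair(group_i=i, group_j=j,
                                   mean_difference=float(hsd.statistic[i, j]),
                                   p_adjusted=p_adj,
                                   significant=p_adj < alpha))
    return AnovaTable(ss_between=ss_between, ss_within=ss_within,
                      df_between=df_between, df_within=df_within,
                      F=f_stat, p_value=p, tukey=tuple(pairs), alpha=alpha)


def p_to_stars(p: float, symbol: str = "*") -> str:
    """Render the usual significance marks at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return symbol * 3
    if p < 0.01:
        return symbol * 2
    if p < 0.05:
        return symbol
    return "ns"
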