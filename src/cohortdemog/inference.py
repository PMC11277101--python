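"""Two-group statistical battery for cohort comparisons.

Conventions chosen to match common rearing-study practice (SPSS-era
defaults): Pearson chi-square without continuity correction, Student's
pooled-variance t, Levene's test on deviations from group means,
Mann-Whitney U reported as min(U1, U2) with exact small-sample p-values,
and the exact binomial sex-ratio test with a Clopper-Pearson interval.
All p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "pearson_chi2_2x2",
    "exact_binomial",
    "pooled_t_test",
    "levene_test",
    "mann_whitney_u",
    "shapiro_normality",
]


@dataclass
class TestResult:
    """A generic test outcome: statistic, df, two-sided p, sample sizes."""

    method: str
    statistic: float
    p: float
    df: Optional[float] = None
    n_per_group: Optional[tuple[int, ...]] = None
    ci: Optional[tuple[float, float]] = None
    note: str = ""

    def __post_init__(self):
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0,1]")
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError("confidence interval bounds out of order")

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df = 1.

    No Yates continuity correction.  Rows are groups, columns outcomes
    (e.g. survived/died per diet).  Degenerate margins raise ValueError.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult("pearson_chi2", float(chi2), float(p), df=float(df),
                      n_per_group=(a + b, c + d))


def exact_binomial(k: int, n: int, p0: float = 0.5,
                   conf_level: float = 0.95) -> TestResult:
    """Exact two-sided binomial test of k successes in n trials vs p0.

    For p0 = 0.5 the two-sided p equals twice the smaller tail (capped
    at 1), which coincides with the minimum-likelihood rule because the
    null pmf is symmetric.  A Clopper-Pearson interval for k/n is
    attached.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError("require 0 <= k <= n, n >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0,1)")
    bt = stats.binomtest(k, n, p0)
    ci = bt.proportion_ci(confidence_level=conf_level, method="exact")
    return TestResult("exact_binomial", float(k / n), float(bt.pvalue),
                      n_per_group=(n,), ci=(float(ci.low), float(ci.high)),
                      note=f"null p0={p0}, Clopper-Pearson {conf_level:.0%} CI")


def pooled_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Student's two-sample t with pooled variance, df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = len(x) + len(y) - 2
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if x.mean() == y.mean():
            return TestResult("pooled_t", 0.0, 1.0, df=float(df),
                              n_per_group=(len(x), len(y)),
                              note="zero pooled variance, equal means")
        return TestResult("pooled_t", math.inf, 0.0, df=float(df),
                          n_per_group=(len(x), len(y)),
                          note="zero pooled variance, unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TestResult("pooled_t", float(t), float(p), df=float(df),
                      n_per_group=(len(x), len(y)))


def levene_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Levene's homogeneity-of-variance test on deviations from group means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return TestResult("levene", 0.0, 1.0,
                          df=float(len(x) + len(y) - 2),
                          n_per_group=(len(x), len(y)),
                          note="no within-group variation")
    w, p = stats.levene(x, y, center="mean")
    return TestResult("levene", float(w), float(p),
                      df=float(len(x) + len(y) - 2),
                      n_per_group=(len(x), len(y)))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U, reported as min(U1, U2), with midrank ties.

    The p-value is exact (full enumeration of rank assignments) when
    n1*n2 <= 400 and the pooled sample has no ties; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs at least 1 observation")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) * len(y) <= 400) and not has_ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    u1 = float(res.statistic)
    u = min(u1, len(x) * len(y) - u1)
    return TestResult("mann_whitney_u", u, float(res.pvalue),
                      n_per_group=(len(x), len(y)),
                      note="exact" if exact else "normal approximation")


def shapiro_normality(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test for one sample (test-selection gate)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return TestResult("shapiro_wilk", math.nan, math.nan,
                          n_per_group=(len(x),),
                          note="too few values or no variation; "
                               "normality not assessable")
    w, p = stats.shapiro(x)
    return TestResult("shapiro_wilk", float(w), float(p),
                      n_per_group=(len(x),))
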