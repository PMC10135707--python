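"""Cohort-comparison statistics for the stage-I feasibility analysis.

Group contrasts between difficult and non-difficult patients: Pearson
chi-squared (without continuity correction) for 2x2 categorical tables,
pooled-variance two-sample t from summary statistics for normally summarised
continuous variables, and the Mann-Whitney rank test for skewed ones.
Fisher's exact test is provided for tables with small expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "pearson_chi2_2x2",
    "fisher_exact_2x2",
    "t_test_from_summary",
    "mann_whitney",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Four nonnegative integer cells: rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.n == 0:
            raise ValueError("table must count at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None


def pearson_chi2_2x2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-squared on a 2x2 table, no continuity correction, 1 df."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ConfigurationError("degenerate table: a row or column margin is zero")
    chi2, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    if (expected <= 0).any():
        raise ConfigurationError("expected counts must be positive")
    return TestResult(statistic=float(chi2), p_value=float(p), df=float(dof))


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Fisher's exact test (two-sided) for tables with small expected counts."""
    odds, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p))


def t_test_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled-variance two-sample t-test from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), df=float(n1 + n2 - 2))


def mann_whitney(sample1: Sequence[float], sample2: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration for small tie-free samples (n <= 8 per group),
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    small = x.size <= 8 and y.size <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)))
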