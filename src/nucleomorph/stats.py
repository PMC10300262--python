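"""Group-comparison tests used in the downstream summaries.

All tests are two-sided: unpaired t test, Mann-Whitney U, Wilcoxon
signed-rank (zero differences dropped, Wilcoxon's convention) and the
chi-squared test on an r x c count table (no continuity correction by
default).  A significance display threshold of alpha = 0.05 is used in
reports; no multiple-testing correction is applied — callers comparing
many conditions should correct externally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "compare_groups", "ALPHA"]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def compare_groups(x, y=None, test: str = "t", **kwargs) -> TestResult:
    """Dispatch a named two-sided test.

    ``t`` and ``mann_whitney`` take two independent samples (n >= 2
    each); ``wilcoxon_signed_rank`` takes paired samples of equal length
    (all-zero differences are a degenerate case and raise);
    ``chi_squared`` takes a single r x c count table as ``x``.
    """
    if test == "chi_squared":
        table = np.asarray(x, dtype=float)
        if table.ndim != 2:
            raise ValueError("chi-squared needs an r x c count table")
        correction = kwargs.get("continuity_correction", False)
        expected = sps.contingency.expected_freq(table)
        if np.any(expected == 0):
            raise ValueError("chi-squared expected count of zero; collapse categories")
        stat, p, _, _ = sps.chi2_contingency(table, correction=correction)
        return TestResult(
            test="chi_squared",
            statistic=float(stat),
            p_value=float(p),
            n_per_group=tuple(int(t) for t in table.sum(axis=1)),
        )

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test == "t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t test needs n >= 2 per group")
        stat, p = sps.ttest_ind(x, y)
    elif test == "mann_whitney":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("Mann-Whitney needs n >= 2 per group")
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        stat, p = res.statistic, res.pvalue
    elif test == "wilcoxon_signed_rank":
        if len(x) != len(y):
            raise ValueError("Wilcoxon signed-rank needs paired samples of equal length")
        diffs = x - y
        if np.all(diffs == 0):
            raise ValueError(
                "all paired differences are zero: Wilcoxon statistic undefined"
            )
        stat, p = sps.wilcoxon(x, y, zero_method="wilcox")
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(
        test=test,
        statistic=float(stat),
        p_value=float(p),
        n_per_group=(len(x), len(y)),
    )
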