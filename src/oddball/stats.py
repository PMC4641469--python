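"""Group comparisons following the experimental statistics decision tree.

For sample sizes of 30 or more per group, Student's t-test is applied
directly.  For smaller samples, each group is first checked for normality
(Kolmogorov-Smirnov with estimated moments, i.e. the Lilliefors variant);
if any group fails, a rank-based test is used instead -- Wilcoxon
signed-rank for paired samples, Wilcoxon rank-sum (Mann-Whitney) otherwise.
Bonferroni correction multiplies the p-value by the number of comparisons,
capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors


@dataclass
class TestReport:
    """Outcome of a two-group comparison."""

    test_name: str
    statistic: float
    pvalue: float  # uncorrected
    pvalue_corrected: float
    sides: int
    paired: bool
    n1: int
    n2: int
    n_comparisons: int

    @property
    def significant(self) -> bool:
        return self.pvalue_corrected < 0.05


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if np.std(x) == 0:
        return False  # degenerate; route to the rank branch
    _, p = lilliefors(x, dist="norm")
    return p >= alpha


def compare_groups(sample1, sample2, paired: bool = False, sides: int = 2,
                   n_comparisons: int = 1) -> TestReport:
    """Compare two samples with the test the protocol prescribes.

    Parameters
    ----------
    sample1, sample2 : array-like
        The two groups; equal length required when ``paired``.
    paired : bool
        Paired (within-unit) or independent comparison.
    sides : {1, 2}
        One- or two-sided alternative; one-sided tests take the alternative
        ``sample1 > sample2``.
    n_comparisons : int
        Bonferroni factor (C); the corrected p is ``min(1, p * C)``.

    Returns
    -------
    TestReport
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if paired and x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    alternative = "greater" if sides == 1 else "two-sided"

    if min(x.size, y.size) >= 30:
        if paired:
            res = sps.ttest_rel(x, y, alternative=alternative)
            name = "paired t-test"
        else:
            res = sps.ttest_ind(x, y, alternative=alternative)
            name = "t-test"
        stat, p = float(res.statistic), float(res.pvalue)
    elif _is_normal(x) and _is_normal(y):
        if paired:
            res = sps.ttest_rel(x, y, alternative=alternative)
            name = "paired t-test"
        else:
            res = sps.ttest_ind(x, y, alternative=alternative)
            name = "t-test"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if paired:
            d = x - y
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                res = sps.wilcoxon(d, alternative=alternative)
                stat, p = float(res.statistic), float(res.pvalue)
            name = "signed-rank"
        else:
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                stat, p = float(x.size * y.size / 2), 1.0
            else:
                res = sps.mannwhitneyu(x, y, alternative=alternative)
                stat, p = float(res.statistic), float(res.pvalue)
            name = "rank-sum"
    return TestReport(test_name=name, statistic=stat, pvalue=p,
                      pvalue_corrected=min(1.0, p * n_comparisons),
                      sides=sides, paired=paired, n1=int(x.size),
                      n2=int(y.size), n_comparisons=n_comparisons)
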