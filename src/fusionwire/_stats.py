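"""Shared two-sample statistics (Welch t, Mann-Whitney U)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    df: float
    pvalue: float


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    pvalue: float


def welch_t(a, b) -> WelchResult:
    """Two-tailed Welch t test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch t test needs n >= 2 in each group")
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if np.isnan(t):  # both groups constant and equal: no evidence of difference
        t, p = 0.0, 1.0
    return WelchResult(statistic=t, df=df, pvalue=p)


def mann_whitney(a, b) -> RankSumResult:
    """Two-sided Mann-Whitney U."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Mann-Whitney needs n >= 2 in each group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RankSumResult(statistic=float(res.statistic), pvalue=float(res.pvalue))
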