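"""Correlation, trending concordance, and the group/time comparisons.

Routing between parametric and rank tests follows the usual convention:
Shapiro-Wilk at alpha = 0.05 on the relevant sample (the paired
differences, or each group) decides between the t-test and the
corresponding rank test; the result records which test ran so reports
are auditable.

Four-quadrant concordance: paired percent changes agreeing in sign,
after excluding pairs where *both* changes are smaller in magnitude
than the central exclusion zone (default 10%, the common convention
for trending analysis of cardiac output monitors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "ComparisonResult",
    "linear_r2",
    "four_quadrant_concordance",
    "compare_paired",
    "compare_groups",
]

_NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class ConcordanceResult:
    """Four-quadrant concordance of two trending measurements."""

    rate: float            # % of remaining pairs with agreeing sign
    n_used: int            # pairs after central exclusion
    n_total: int
    exclusion_pct: float   # half-width of the exclusion square


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p: float
    test_used: str  # "paired_t", "wilcoxon_signed_rank", "welch_t",
    #                 "rank_sum", "degenerate"


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def linear_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r-squared with the two-sided t-test p-value."""
    x, y = _pairwise_complete(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


def four_quadrant_concordance(
    dx: Sequence[float],
    dy: Sequence[float],
    exclusion: float = 10.0,
) -> ConcordanceResult:
    """Direction-of-change agreement between two paired change series."""
    dx, dy = _pairwise_complete(dx, dy)
    n_total = dx.size
    keep = ~((np.abs(dx) < exclusion) & (np.abs(dy) < exclusion))
    dx, dy = dx[keep], dy[keep]
    if dx.size == 0:
        raise ValueError("all pairs fall inside the exclusion zone")
    concordant = np.sign(dx) == np.sign(dy)
    return ConcordanceResult(rate=float(concordant.mean() * 100.0),
                             n_used=int(dx.size), n_total=int(n_total),
                             exclusion_pct=float(exclusion))


def _is_normal(sample: np.ndarray) -> bool:
    if np.ptp(sample) == 0:
        return False
    return stats.shapiro(sample).pvalue >= _NORMALITY_ALPHA


def compare_paired(
    before: Sequence[float], after: Sequence[float]
) -> ComparisonResult:
    """Paired t-test when the differences look normal, Wilcoxon
    signed-rank otherwise.  All-zero differences are degenerate (p=1)."""
    b, a = _pairwise_complete(before, after)
    if b.size < 3:
        raise ValueError("need at least 3 complete pairs")
    d = a - b
    if np.all(d == 0):
        return ComparisonResult(statistic=0.0, p=1.0, test_used="degenerate")
    if _is_normal(d):
        res = stats.ttest_rel(a, b)
        return ComparisonResult(float(res.statistic), float(res.pvalue),
                                "paired_t")
    res = stats.wilcoxon(a, b)
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            "wilcoxon_signed_rank")


def compare_groups(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Welch two-sample t-test when both groups look normal, two-sided
    rank-sum (Mann-Whitney) otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return ComparisonResult(statistic=0.0, p=1.0, test_used="degenerate")
    if a.size >= 3 and b.size >= 3 and _is_normal(a) and _is_normal(b):
        res = stats.ttest_ind(a, b, equal_var=False)
        return ComparisonResult(float(res.statistic), float(res.pvalue),
                                "welch_t")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            "rank_sum")


def format_p(p: float) -> str:
    """Two decimals above 0.001, "<0.001" below."""
    return "<0.001" if p < 0.001 else f"{p:.2f}"
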