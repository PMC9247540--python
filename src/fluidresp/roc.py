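"""Empirical ROC curves, DeLong AUC inference, and Youden cutoffs.

The AUC is the Mann-Whitney pair statistic: the fraction of
(positive, negative) score pairs correctly ordered, counting ties as
half.  Confidence intervals and paired AUC comparisons use DeLong's
nonparametric structural-components variance with midranks for ties,
so no distributional assumption is made about the marker.

Cutoff semantics: a test is *positive* when ``score >= cutoff``
(``higher_is_positive``) or ``score <= cutoff`` (``lower_is_positive``).
Candidate cutoffs are the midpoints between adjacent distinct observed
values plus infinite sentinels, so the reported "cutoff >= c" matches
how clinical thresholds are quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Direction",
    "RocResult",
    "CutoffResult",
    "DegenerateLabelsError",
    "VarianceUndefinedError",
    "empirical_roc",
    "delong_ci",
    "delong_paired_test",
    "youden_best_cutoff",
]

Direction = Literal["higher_is_positive", "lower_is_positive"]


class DegenerateLabelsError(ValueError):
    """The label vector does not contain both classes."""


class VarianceUndefinedError(ValueError):
    """DeLong variance needs at least two observations per class."""


def _clean(scores, labels, direction: Direction = "higher_is_positive"):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if not (y.any() and (~y).any()):
        raise DegenerateLabelsError(
            "need at least one positive and one negative label")
    if direction == "lower_is_positive":
        s = -s
    return s, y


def _placements(s: np.ndarray, y: np.ndarray):
    """DeLong structural components (placement values) via midranks."""
    pos, neg = s[y], s[~y]
    m, n = pos.size, neg.size
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (all_r[:m] - stats.rankdata(pos)) / n          # per positive
    v01 = 1.0 - (all_r[m:] - stats.rankdata(neg)) / m    # per negative
    auc = v10.mean()
    return auc, v10, v01


@dataclass
class RocResult:
    """An empirical ROC curve with its AUC and 95% CI.

    ``thresholds`` are the sorted distinct marker values bracketed by
    -inf/+inf sentinels; ``sens``/``spec`` are evaluated with the
    test-positive rule at each threshold.  ``auc_ci`` is ``None`` when
    the DeLong variance is undefined (fewer than two observations in a
    class).
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_ci: Optional[tuple[float, float]]
    direction: Direction
    n_pos: int
    n_neg: int


@dataclass
class CutoffResult:
    """The Youden-index-optimal cutoff and its operating point."""

    cutoff: float
    youden_j: float
    sens: float
    spec: float
    direction: Direction


def empirical_roc(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: Direction = "higher_is_positive",
    level: float = 0.95,
) -> RocResult:
    """Empirical ROC curve with Mann-Whitney AUC and DeLong CI.

    Pairs with non-finite scores are dropped (pairwise-complete).
    Raises :class:`DegenerateLabelsError` when only one class remains.
    """
    s, y = _clean(scores, labels, direction)
    auc, v10, v01 = _placements(s, y)

    u = np.unique(s)
    thresholds = np.concatenate([[-np.inf], u, [np.inf]])
    # counts of scores >= t for each threshold t
    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    m, n = pos_sorted.size, neg_sorted.size
    tp = m - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n - np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / m
    spec = 1.0 - fp / n

    if direction == "lower_is_positive":
        thresholds = -thresholds[::-1]
        sens = sens[::-1]
        spec = spec[::-1]

    try:
        ci = delong_auc_ci(auc, v10, v01, level)
    except VarianceUndefinedError:
        ci = None
    return RocResult(thresholds=thresholds, sens=sens, spec=spec,
                     auc=float(auc), auc_ci=ci, direction=direction,
                     n_pos=m, n_neg=n)


def delong_auc_ci(
    auc: float, v10: np.ndarray, v01: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation CI from precomputed placement values."""
    if v10.size < 2 or v01.size < 2:
        raise VarianceUndefinedError(
            "DeLong variance needs >= 2 observations per class")
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def delong_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: Direction = "higher_is_positive",
    level: float = 0.95,
) -> tuple[float, float]:
    """DeLong CI for the AUC of one marker, truncated to [0, 1]."""
    s, y = _clean(scores, labels, direction)
    auc, v10, v01 = _placements(s, y)
    return delong_auc_ci(auc, v10, v01, level)


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
    direction: Direction = "higher_is_positive",
) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two markers on the same patients.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided p-value.  Only
    patients with both markers observed enter (pairwise-complete
    intersection); a marker compared with itself, or with any strictly
    monotone transform of itself, gives z = 0 and p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b, y = a[keep], b[keep], y[keep]
    if not (y.any() and (~y).any()):
        raise DegenerateLabelsError(
            "need at least one positive and one negative label")
    if y.sum() < 2 or (~y).sum() < 2:
        raise VarianceUndefinedError(
            "paired DeLong needs >= 2 complete pairs per class")
    if direction == "lower_is_positive":
        a, b = -a, -b
    auc_a, v10_a, v01_a = _placements(a, y)
    auc_b, v10_b, v01_b = _placements(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if abs(diff) < 1e-12 else math.inf * math.copysign(1, diff)
    else:
        z = diff / math.sqrt(var)
    p = 1.0 if not math.isfinite(z) and abs(diff) < 1e-12 else \
        float(2.0 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    return float(auc_a), float(auc_b), float(z), p


def _candidate_cutoffs(u: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct sorted values plus sentinels."""
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _youden_scan(s: np.ndarray, y: np.ndarray):
    """J over all candidate cutoffs on a higher-is-positive scale.

    Returns (cutoffs ascending, sens, spec); vectorized, used by the
    bootstrap gray-zone machinery as well.
    """
    u = np.unique(s)
    cuts = _candidate_cutoffs(u)
    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    m, n = pos_sorted.size, neg_sorted.size
    tp = m - np.searchsorted(pos_sorted, cuts, side="left")
    fp = n - np.searchsorted(neg_sorted, cuts, side="left")
    return cuts, tp / m, 1.0 - fp / n


def youden_best_cutoff(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: Direction = "higher_is_positive",
) -> CutoffResult:
    """Maximize J = Sn + Sp - 1 over all attainable cutoffs.

    Ties in J are broken toward higher sensitivity, i.e. the least
    stringent cutoff attaining the maximum.
    """
    s, y = _clean(scores, labels, direction)
    cuts, sens, spec = _youden_scan(s, y)
    j = sens + spec - 1.0
    k = int(np.argmax(j))  # first (smallest) maximizer: highest sens
    cutoff = cuts[k]
    if direction == "lower_is_positive":
        cutoff = -cutoff
    return CutoffResult(cutoff=float(cutoff), youden_j=float(j[k]),
                        sens=float(sens[k]), spec=float(spec[k]),
                        direction=direction)


def plot_roc(roc: RocResult, ax=None, label: Optional[str] = None):
    """Plot one empirical ROC curve (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    order = np.argsort(1.0 - roc.spec)
    ax.plot((1.0 - roc.spec)[order], roc.sens[order], drawstyle="steps-post",
            label=label or f"AUC = {roc.auc:.2f}")
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax
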