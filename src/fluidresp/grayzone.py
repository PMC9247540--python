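"""Gray-zone (inconclusive-interval) estimation for a diagnostic marker.

Two constructions are computed and the *wider* one is reported:

1. **Bootstrap of the optimal cutoff** — patients are resampled with
   replacement (whole-cohort, non-stratified by default), the
   Youden-optimal cutoff is recomputed on each of ``n_boot`` replicates,
   and the gray zone is the percentile interval of those cutoffs.
   Replicates that draw a single class are redrawn so exactly
   ``n_boot`` cutoffs enter the percentiles.
2. **Triadic (three-class) zone** — marker values below the largest
   cutoff keeping sensitivity >= a floor (default 90%) rule *out*
   responsiveness; values above the smallest cutoff reaching the
   specificity floor rule it *in*; the remaining middle band is
   inconclusive.  If the two bounds cross the zone is empty.

Fractions of the analysis cohort falling below / inside / above the
zone are reported; zone membership is the closed interval
``lower <= score <= upper``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .roc import (
    Direction,
    DegenerateLabelsError,
    _clean,
    _youden_scan,
)

__all__ = [
    "GrayZone",
    "GrayZoneSettings",
    "bootstrap_cutoff_zone",
    "triadic_zone",
    "combined_zone",
]


@dataclass(frozen=True)
class GrayZone:
    """An inconclusive marker interval and the cohort's decision split.

    ``fractions`` is ``(below, inside, above)`` on the analysis cohort
    and always sums to 1.
    """

    lower: float
    upper: float
    method: str  # "bootstrap", "triadic" or "combined"
    fractions: tuple[float, float, float]
    n_boot: Optional[int] = None
    redrawn_replicates: int = 0
    bootstrap_zone: Optional["GrayZone"] = None
    triadic_zone: Optional["GrayZone"] = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class GrayZoneSettings:
    """Knobs for the combined gray-zone procedure."""

    n_boot: int = 1000
    level: float = 0.95
    seed: Optional[int] = None
    sn_floor: float = 0.90
    sp_floor: float = 0.90
    stratified: bool = False


def _fractions(scores: np.ndarray, lower: float, upper: float
               ) -> tuple[float, float, float]:
    n = scores.size
    below = float((scores < lower).sum()) / n
    inside = float(((scores >= lower) & (scores <= upper)).sum()) / n
    above = float((scores > upper).sum()) / n
    return (below, inside, above)


def bootstrap_cutoff_zone(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    direction: Direction = "higher_is_positive",
    stratified: bool = False,
) -> GrayZone:
    """Percentile interval of the Youden-best cutoff over bootstrap
    replicates; deterministic given ``seed``."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    s, y = _clean(scores, labels, direction)
    n = s.size
    rng = np.random.default_rng(seed)
    cutoffs = np.empty(n_boot)
    redrawn = 0
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    for b in range(n_boot):
        while True:
            if stratified:
                idx = np.concatenate([
                    rng.choice(pos_idx, size=pos_idx.size, replace=True),
                    rng.choice(neg_idx, size=neg_idx.size, replace=True),
                ])
            else:
                idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.any() and (~yb).any():
                break
            redrawn += 1
        cuts, sens, spec = _youden_scan(s[idx], yb)
        cutoffs[b] = cuts[int(np.argmax(sens + spec - 1.0))]
    alpha = 1.0 - level
    # outward nearest-rank percentiles: robust to infinite replicate
    # cutoffs (a replicate whose best J sits at a sentinel)
    lo = float(np.quantile(cutoffs, alpha / 2, method="lower"))
    hi = float(np.quantile(cutoffs, 1.0 - alpha / 2, method="higher"))
    if direction == "lower_is_positive":
        lo, hi = -hi, -lo
        s = -s
    return GrayZone(lower=float(lo), upper=float(hi), method="bootstrap",
                    fractions=_fractions(s, float(lo), float(hi)),
                    n_boot=n_boot, redrawn_replicates=redrawn)


def triadic_zone(
    scores: Sequence[float],
    labels: Sequence[bool],
    sn_floor: float = 0.90,
    sp_floor: float = 0.90,
    direction: Direction = "higher_is_positive",
) -> GrayZone:
    """Three-class zone from sensitivity and specificity floors.

    Lower bound: the largest candidate cutoff whose sensitivity is
    still >= ``sn_floor`` (below it the marker rules responsiveness
    out).  Upper bound: the smallest cutoff whose specificity reaches
    ``sp_floor`` (above it the marker rules responsiveness in).
    Crossed bounds collapse to an empty zone at their midpoint.
    """
    s, y = _clean(scores, labels, direction)
    cuts, sens, spec = _youden_scan(s, y)
    lo_candidates = cuts[sens >= sn_floor]
    hi_candidates = cuts[spec >= sp_floor]
    lower = float(lo_candidates.max()) if lo_candidates.size else -math.inf
    upper = float(hi_candidates.min()) if hi_candidates.size else math.inf
    if lower >= upper:  # crossed: empty zone
        mid = (lower + upper) / 2.0
        if not math.isfinite(mid):
            fin = [v for v in (lower, upper) if math.isfinite(v)]
            mid = fin[0] if fin else float(np.median(s))
            mid = float(np.clip(mid, s.min(), s.max()))
        lower = upper = mid
    if direction == "lower_is_positive":
        lower, upper = -upper, -lower
        s = -s
    return GrayZone(lower=lower, upper=upper, method="triadic",
                    fractions=_fractions(s, lower, upper))


def combined_zone(
    scores: Sequence[float],
    labels: Sequence[bool],
    settings: GrayZoneSettings = GrayZoneSettings(),
    direction: Direction = "higher_is_positive",
) -> GrayZone:
    """The wider of the bootstrap and triadic zones (ties favour the
    triadic zone), with both components attached."""
    boot = bootstrap_cutoff_zone(
        scores, labels, n_boot=settings.n_boot, level=settings.level,
        seed=settings.seed, direction=direction,
        stratified=settings.stratified)
    tri = triadic_zone(scores, labels, sn_floor=settings.sn_floor,
                       sp_floor=settings.sp_floor, direction=direction)
    winner = boot if boot.width > tri.width else tri
    return GrayZone(lower=winner.lower, upper=winner.upper, method="combined",
                    fractions=winner.fractions, n_boot=boot.n_boot,
                    redrawn_replicates=boot.redrawn_replicates,
                    bootstrap_zone=boot, triadic_zone=tri)
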