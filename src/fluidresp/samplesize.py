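"""ROC sample-size planning by Obuchowski's binormal variance method.

The number of positives needed to detect an AUC of ``auc_alt`` against
a null value ``auc_null`` with ``R`` negatives per positive is

    n_pos = ( z_alpha * sqrt(V(auc_null)) + z_power * sqrt(V(auc_alt)) )^2
            / (auc_alt - auc_null)^2

with the equal-variance binormal variance function

    V(A) = 0.0099 * exp(-a^2/2) * [ (5 a^2 + 8) + (a^2 + 8) / R ],
    a = sqrt(2) * PhiInv(A),

which at the null A = 0.5 reduces exactly to 0.0099 * (8 + 8/R).
The total is rounded half-up *after* multiplying by (1 + R); the
per-group counts are then re-derived from the total and the ratio.
The default is a one-sided alternative (AUC above the null); a
two-sided option uses z at alpha/2 and yields a larger n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import stats

from .diagnostics import round_half_up

__all__ = ["RocSampleSizeSpec", "SampleSizeResult", "obuchowski_variance",
           "obuchowski_n", "inflate_for_dropout"]


@dataclass(frozen=True)
class RocSampleSizeSpec:
    """Planning inputs for testing one ROC AUC against a null value."""

    auc_alt: float
    auc_null: float = 0.5
    ratio_neg_pos: float = 1.0
    alpha: float = 0.05
    power: float = 0.90
    sided: Literal["one", "two"] = "one"

    def __post_init__(self) -> None:
        if not (0.5 <= self.auc_null < self.auc_alt < 1.0):
            raise ValueError("need 0.5 <= auc_null < auc_alt < 1")
        if self.ratio_neg_pos <= 0:
            raise ValueError("ratio_neg_pos must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must be in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


@dataclass(frozen=True)
class SampleSizeResult:
    n_pos: int
    n_neg: int
    n_total: int
    n_pos_raw: float


def obuchowski_variance(auc: float, ratio_neg_pos: float) -> float:
    """Binormal variance function V(A) for one positive subject."""
    a = math.sqrt(2.0) * float(stats.norm.ppf(auc))
    return 0.0099 * math.exp(-a * a / 2.0) * (
        (5.0 * a * a + 8.0) + (a * a + 8.0) / ratio_neg_pos)


def obuchowski_n(spec: RocSampleSizeSpec) -> SampleSizeResult:
    """Positives and total required for the specified ROC test."""
    r = spec.ratio_neg_pos
    alpha = spec.alpha / 2.0 if spec.sided == "two" else spec.alpha
    z_a = float(stats.norm.ppf(1.0 - alpha))
    z_b = float(stats.norm.ppf(spec.power))
    v0 = obuchowski_variance(spec.auc_null, r)
    v1 = obuchowski_variance(spec.auc_alt, r)
    delta = spec.auc_alt - spec.auc_null
    n_pos_raw = (z_a * math.sqrt(v0) + z_b * math.sqrt(v1)) ** 2 / delta ** 2
    n_total = int(round_half_up(n_pos_raw * (1.0 + r), 0))
    n_pos = int(round_half_up(n_total / (1.0 + r), 0))
    return SampleSizeResult(n_pos=n_pos, n_neg=n_total - n_pos,
                            n_total=n_total, n_pos_raw=n_pos_raw)


def inflate_for_dropout(n: int, dropout: float) -> int:
    """Smallest enrolment such that (1 - dropout) of it still leaves n."""
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    return math.ceil(n / (1.0 - dropout))
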