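"""2x2 classification at a cutoff and diagnostic metrics with CIs.

Proportions (sensitivity, specificity, predictive values) carry exact
Clopper-Pearson intervals computed from the beta-quantile
representation of the inverted binomial tails.  Likelihood ratios carry
the standard log-method interval,

    exp( ln LR +- z * sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn)) )

for LR+ and the analogous expression (fn/tn in place of tp/fp) for
LR-.  When a zero cell makes the log-method SE undefined, a 0.5
continuity correction is applied to all four cells *for the CI only*,
with a warning; the point estimate keeps the raw counts.  Display
rounding is round-half-up to one decimal for percentages and two
decimals for ratios, matching how such results are quoted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .roc import Direction, DegenerateLabelsError

__all__ = [
    "TwoByTwo",
    "MetricWithCI",
    "DiagnosticSummary",
    "classify_at_cutoff",
    "proportion_ci_exact",
    "likelihood_ratio_ci",
    "diagnostic_summary",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 92.25 -> 92.3 at one decimal)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoByTwo:
    """Classification counts: tp/fn partition the positives (responders),
    fp/tn the negatives."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class MetricWithCI:
    """A point estimate with its confidence interval and CI method."""

    estimate: float
    ci: tuple[float, float]
    method: Literal["clopper_pearson", "log_method"]

    def scaled(self, factor: float = 100.0) -> tuple[float, float, float]:
        return (self.estimate * factor, self.ci[0] * factor, self.ci[1] * factor)


def classify_at_cutoff(
    scores: Sequence[float],
    labels: Sequence[bool],
    cutoff: float,
    direction: Direction = "higher_is_positive",
) -> TwoByTwo:
    """Count the 2x2 table for the rule "test-positive iff score >= cutoff"
    (or <= for ``lower_is_positive``).  Missing scores are dropped."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if not (y.any() and (~y).any()):
        raise DegenerateLabelsError(
            "need at least one positive and one negative label")
    test_pos = s >= cutoff if direction == "higher_is_positive" else s <= cutoff
    return TwoByTwo(
        tp=int((test_pos & y).sum()),
        fn=int((~test_pos & y).sum()),
        fp=int((test_pos & ~y).sum()),
        tn=int((~test_pos & ~y).sum()),
    )


def proportion_ci_exact(
    successes: int, trials: int, level: float = 0.95
) -> MetricWithCI:
    """Exact (Clopper-Pearson) binomial interval.

    Lower bound is exactly 0 when ``successes == 0`` and the upper bound
    exactly 1 when ``successes == trials``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    alpha = 1.0 - level
    k, n = successes, trials
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return MetricWithCI(estimate=k / n, ci=(lo, hi), method="clopper_pearson")


def _lr_ci(lr: float, cells: tuple[int, int, int, int],
           level: float) -> tuple[float, float]:
    """Log-method CI; cells = (num_hit, num_total, den_hit, den_total)."""
    a, m, b, n = cells
    if min(a, b) == 0 or a == m or b == n:
        warnings.warn(
            "zero/full cell: 0.5 continuity correction applied to the "
            "likelihood-ratio CI (point estimate unchanged)",
            stacklevel=3)
        a, m, b, n = a + 0.5, m + 1.0, b + 0.5, n + 1.0
        lr = (a / m) / (b / n)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(1 / a - 1 / m + 1 / b - 1 / n)
    return (math.exp(math.log(lr) - z * se), math.exp(math.log(lr) + z * se))


def likelihood_ratio_ci(
    t: TwoByTwo, which: Literal["positive", "negative"], level: float = 0.95
) -> MetricWithCI:
    """Likelihood ratio with its log-method CI.

    LR+ = Sn/(1-Sp); LR- = (1-Sn)/Sp.  A perfectly specific test gives
    an infinite LR+ with an open upper CI bound.
    """
    sn = t.tp / t.n_pos
    sp = t.tn / t.n_neg
    if which == "positive":
        if sp == 1.0:
            return MetricWithCI(math.inf, (math.nan, math.inf), "log_method")
        lr = sn / (1.0 - sp)
        ci = _lr_ci(lr, (t.tp, t.n_pos, t.fp, t.n_neg), level)
    else:
        if sp == 0.0:
            return MetricWithCI(math.inf, (math.nan, math.inf), "log_method")
        lr = (1.0 - sn) / sp
        ci = _lr_ci(lr, (t.fn, t.n_pos, t.tn, t.n_neg), level)
    return MetricWithCI(estimate=lr, ci=ci, method="log_method")


@dataclass(frozen=True)
class DiagnosticSummary:
    """All standard diagnostic metrics at one cutoff."""

    table: TwoByTwo
    sens: MetricWithCI
    spec: MetricWithCI
    ppv: MetricWithCI
    npv: MetricWithCI
    lr_pos: MetricWithCI
    lr_neg: MetricWithCI
    prevalence: float
    level: float

    def formatted(self) -> dict[str, str]:
        """One-decimal percentages / two-decimal ratios, as quoted in
        clinical reports."""
        def pct(m: MetricWithCI) -> str:
            e, lo, hi = m.scaled(100.0)
            return (f"{round_half_up(e, 1)}% "
                    f"(95% CI, {round_half_up(lo, 1)}-{round_half_up(hi, 1)}%)")

        def ratio(m: MetricWithCI) -> str:
            return (f"{round_half_up(m.estimate, 2)} "
                    f"(95% CI, {round_half_up(m.ci[0], 2)}-"
                    f"{round_half_up(m.ci[1], 2)})")

        return {"sensitivity": pct(self.sens), "specificity": pct(self.spec),
                "ppv": pct(self.ppv), "npv": pct(self.npv),
                "lr_pos": ratio(self.lr_pos), "lr_neg": ratio(self.lr_neg)}


def diagnostic_summary(t: TwoByTwo, level: float = 0.95) -> DiagnosticSummary:
    """Sn/Sp/PPV/NPV with exact CIs and LR+/LR- with log-method CIs."""
    if t.n_pos == 0 or t.n_neg == 0:
        raise DegenerateLabelsError("need both positives and negatives")

    def prop(k: int, n: int) -> MetricWithCI:
        if n == 0:
            return MetricWithCI(math.nan, (math.nan, math.nan),
                                "clopper_pearson")
        return proportion_ci_exact(k, n, level)

    return DiagnosticSummary(
        table=t,
        sens=prop(t.tp, t.n_pos),
        spec=prop(t.tn, t.n_neg),
        ppv=prop(t.tp, t.tp + t.fp),
        npv=prop(t.tn, t.tn + t.fn),
        lr_pos=likelihood_ratio_ci(t, "positive", level),
        lr_neg=likelihood_ratio_ci(t, "negative", level),
        prevalence=t.n_pos / t.n,
        level=level,
    )
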