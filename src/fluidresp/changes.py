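"""Relative-change statistics and the responder classification rule.

All changes are expressed in percent of the pre-intervention value.
Variables that fall during the recruitment maneuver (PI, SV, CO,
pressures, HR) are reported in decrease form, ``(before-after)/before*100``,
so a positive number means the value dropped; the variation indices
(PPV, PVI, SVV), which rise, use increase form ``(after-before)/before*100``.
A fluid responder is a patient whose stroke volume rises by at least
10% after volume expansion.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .datamodel import (
    LRM_DECREASE_VARS,
    LRM_INCREASE_VARS,
    VE_CHANGE_VARS,
    ChangeSet,
    PatientRecord,
    TimePoint,
)

__all__ = [
    "relative_decrease",
    "relative_increase",
    "derive_changes",
    "classify_responder",
    "baseline_return_check",
    "attach_derived",
    "RESPONDER_THRESHOLD_PCT",
    "BASELINE_RETURN_PCT",
]

#: Stroke-volume rise after volume expansion defining a responder (>=, %).
RESPONDER_THRESHOLD_PCT = 10.0
#: Allowed deviation from baseline before the fluid challenge starts (<, %).
BASELINE_RETURN_PCT = 10.0


def relative_decrease(before: float, after: float) -> float:
    """Percent decrease from ``before`` to ``after``.

    Positive when the value fell; ``before`` must be > 0.
    """
    if before <= 0:
        raise ValueError(f"reference value must be > 0, got {before!r}")
    return (before - after) / before * 100.0


def relative_increase(before: float, after: float) -> float:
    """Percent increase from ``before`` to ``after`` (``before`` > 0)."""
    if before <= 0:
        raise ValueError(f"reference value must be > 0, got {before!r}")
    return (after - before) / before * 100.0


def classify_responder(
    delta_sv_ve: Optional[float],
    threshold: float = RESPONDER_THRESHOLD_PCT,
) -> bool:
    """True iff the stroke-volume rise after VE is >= the threshold.

    The boundary is inclusive: a rise of exactly 10% is a responder.
    """
    if delta_sv_ve is None:
        raise ValueError("cannot classify: delta_sv_ve is missing")
    return delta_sv_ve >= threshold


def baseline_return_check(
    reference: float,
    current: float,
    tolerance_pct: float = BASELINE_RETURN_PCT,
) -> bool:
    """True iff ``current`` is within ``tolerance_pct`` of ``reference``.

    Strict inequality: a deviation of exactly 10% fails the check.
    """
    if reference <= 0:
        raise ValueError(f"reference value must be > 0, got {reference!r}")
    return abs(current - reference) / reference * 100.0 < tolerance_pct


def _maybe(fn, before: Optional[float], after: Optional[float]) -> Optional[float]:
    if before is None or after is None:
        return None
    return fn(before, after)


def derive_changes(record: PatientRecord) -> ChangeSet:
    """Compute the full :class:`~fluidresp.datamodel.ChangeSet` for one patient.

    Missing inputs propagate to missing outputs; nothing is imputed.
    """
    t1, t2 = record.panel(TimePoint.T1), record.panel(TimePoint.T2)
    t3, t4 = record.panel(TimePoint.T3), record.panel(TimePoint.T4)
    values: dict[str, Optional[float]] = {}
    for var in LRM_DECREASE_VARS:
        values[f"delta_{var}_lrm"] = _maybe(
            relative_decrease, t1.value(var), t2.value(var))
    for var in LRM_INCREASE_VARS:
        values[f"delta_{var}_lrm"] = _maybe(
            relative_increase, t1.value(var), t2.value(var))
    for var in VE_CHANGE_VARS:
        values[f"delta_{var}_ve"] = _maybe(
            relative_increase, t3.value(var), t4.value(var))
    return ChangeSet(**values)


def attach_derived(
    records: Sequence[PatientRecord],
    threshold: float = RESPONDER_THRESHOLD_PCT,
) -> Sequence[PatientRecord]:
    """Fill ``changes`` and ``responder`` on each record, in place.

    The responder label is left ``None`` when the VE stroke-volume
    change cannot be computed.
    """
    for rec in records:
        rec.changes = derive_changes(rec)
        dsv = rec.changes.delta_sv_ve
        rec.responder = None if dsv is None else classify_responder(dsv, threshold)
    return records
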