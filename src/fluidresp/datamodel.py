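"""Core domain types and CSV I/O for perioperative hemodynamic cohorts.

A cohort is a table with one row per patient and one column per
(variable, time point) pair.  The four time points bracket the two
interventions of the protocol: T1/T2 before and after the lung
recruitment maneuver (LRM), T3/T4 before and after volume expansion
(VE).  Ten hemodynamic variables are tracked:

====== ============================ =========
key    variable                     units
====== ============================ =========
pi     perfusion index              % (ratio)
sv     stroke volume                mL
co     cardiac output               L/min
sbp    systolic blood pressure      mmHg
dbp    diastolic blood pressure     mmHg
map    mean arterial pressure       mmHg
hr     heart rate                   beats/min
ppv    pulse pressure variation     %
svv    stroke volume variation      %
pvi    pleth variability index      %
====== ============================ =========

CSV schema (the default; a column map may rename): one ``patient_id``
column plus ``<var>_<tp>`` columns, e.g. ``pi_t1`` .. ``pvi_t4``.
Comma separated, UTF-8, ``.`` decimal separator, empty cell = missing.
Values are written with ``repr`` so a write/read cycle is bit-exact.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Optional, Sequence

__all__ = [
    "TimePoint",
    "HemoPanel",
    "ChangeSet",
    "PatientRecord",
    "ValidationError",
    "SchemaError",
    "ParseError",
    "VARIABLES",
    "VARIATION_INDICES",
    "LRM_DECREASE_VARS",
    "LRM_INCREASE_VARS",
    "VE_CHANGE_VARS",
    "read_cohort",
    "write_cohort",
    "cohort_to_dataframe",
]

#: Short variable keys, in canonical column order.
VARIABLES: tuple[str, ...] = (
    "pi", "sv", "co", "sbp", "dbp", "map", "hr", "ppv", "svv", "pvi",
)
#: Respiratory-variation indices: may be zero, everything else must be > 0.
VARIATION_INDICES: frozenset[str] = frozenset({"ppv", "svv", "pvi"})
#: Variables whose LRM change is reported in decrease form.
LRM_DECREASE_VARS: tuple[str, ...] = ("pi", "sv", "co", "sbp", "dbp", "map", "hr")
#: Variables whose LRM change is reported in increase form.
LRM_INCREASE_VARS: tuple[str, ...] = ("ppv", "pvi", "svv")
#: Variables with a reported relative change over volume expansion.
VE_CHANGE_VARS: tuple[str, ...] = ("sv", "co", "map")

_FIELD_BY_VAR: dict[str, str] = {
    "pi": "pi",
    "sv": "sv_ml",
    "co": "co_l_min",
    "sbp": "sbp_mmhg",
    "dbp": "dbp_mmhg",
    "map": "map_mmhg",
    "hr": "hr_bpm",
    "ppv": "ppv_pct",
    "svv": "svv_pct",
    "pvi": "pvi_pct",
}


class ValidationError(ValueError):
    """An input value violates a documented cohort invariant."""


class SchemaError(ValueError):
    """A cohort file header does not match the documented schema."""


class ParseError(ValueError):
    """A cohort file cell could not be parsed as a number."""


class TimePoint(enum.Enum):
    """Measurement time points: before/after LRM, before/after VE."""

    T1 = 1  #: baseline before the recruitment maneuver
    T2 = 2  #: immediately after the recruitment maneuver
    T3 = 3  #: second baseline, before volume expansion
    T4 = 4  #: immediately after volume expansion

    def __lt__(self, other: "TimePoint") -> bool:
        if not isinstance(other, TimePoint):
            return NotImplemented
        return self.value < other.value

    @property
    def key(self) -> str:
        return self.name.lower()


#: MAP consistency tolerance (mmHg) for inputs rounded to the integer.
_MAP_TOL = 1.0


@dataclass
class HemoPanel:
    """One time point's hemodynamic measurements for one patient.

    Any field may be ``None`` (missing).  Present values must be strictly
    positive, except the variation indices (ppv/svv/pvi) which may be 0.
    When systolic, diastolic and mean pressure are all present they must
    satisfy ``dbp <= map <= sbp`` within 1 mmHg (rounded inputs).
    """

    pi: Optional[float] = None
    sv_ml: Optional[float] = None
    co_l_min: Optional[float] = None
    sbp_mmhg: Optional[float] = None
    dbp_mmhg: Optional[float] = None
    map_mmhg: Optional[float] = None
    hr_bpm: Optional[float] = None
    ppv_pct: Optional[float] = None
    svv_pct: Optional[float] = None
    pvi_pct: Optional[float] = None

    def __post_init__(self) -> None:
        for var in VARIABLES:
            v = self.value(var)
            if v is None:
                continue
            v = float(v)
            if var in VARIATION_INDICES:
                if v < 0:
                    raise ValidationError(
                        f"{var} must be >= 0, got {v!r}")
            elif v <= 0:
                raise ValidationError(
                    f"{var} must be strictly positive, got {v!r}")
        s, d, m = self.sbp_mmhg, self.dbp_mmhg, self.map_mmhg
        if s is not None and d is not None and m is not None:
            if not (d - _MAP_TOL <= m <= s + _MAP_TOL):
                raise ValidationError(
                    f"pressure ordering violated: dbp={d}, map={m}, sbp={s}")

    def value(self, var: str) -> Optional[float]:
        """Return the measurement for short variable key ``var``."""
        return getattr(self, _FIELD_BY_VAR[var])

    @classmethod
    def from_values(cls, values: Mapping[str, Optional[float]]) -> "HemoPanel":
        """Build a panel from a ``{short key: value}`` mapping."""
        return cls(**{_FIELD_BY_VAR[k]: v for k, v in values.items()})


@dataclass
class ChangeSet:
    """Per-patient relative changes (% of the pre-intervention value).

    LRM changes are decrease-form for PI/SV/CO/SBP/DBP/MAP/HR
    (positive = the value fell during the maneuver) and increase-form
    for PPV/PVI/SVV (positive = the index rose).  VE changes (SV, CO,
    MAP) are increase-form over T3 -> T4.  A change is missing iff one
    of its two inputs is missing.
    """

    delta_pi_lrm: Optional[float] = None
    delta_sv_lrm: Optional[float] = None
    delta_co_lrm: Optional[float] = None
    delta_sbp_lrm: Optional[float] = None
    delta_dbp_lrm: Optional[float] = None
    delta_map_lrm: Optional[float] = None
    delta_hr_lrm: Optional[float] = None
    delta_ppv_lrm: Optional[float] = None
    delta_pvi_lrm: Optional[float] = None
    delta_svv_lrm: Optional[float] = None
    delta_sv_ve: Optional[float] = None
    delta_co_ve: Optional[float] = None
    delta_map_ve: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class PatientRecord:
    """Four time-point panels plus derived changes and responder label.

    ``changes`` and ``responder`` start as ``None`` and are filled by
    :func:`fluidresp.changes.attach_derived`.  A responder is a patient
    whose stroke volume rose >= 10% after volume expansion.
    """

    patient_id: str
    panels: dict[TimePoint, HemoPanel] = field(default_factory=dict)
    changes: Optional[ChangeSet] = None
    responder: Optional[bool] = None

    def panel(self, tp: TimePoint) -> HemoPanel:
        return self.panels.get(tp, HemoPanel())

    def value(self, var: str, tp: TimePoint) -> Optional[float]:
        return self.panel(tp).value(var)


def default_columns() -> list[str]:
    """The documented column order: patient_id then ``<var>_<tp>``."""
    return ["patient_id"] + [
        f"{var}_{tp.key}" for var in VARIABLES for tp in TimePoint
    ]


def _column_map(schema_config: Optional[Mapping[str, str]]) -> dict[str, str]:
    # maps file column name -> canonical column name
    cols = default_columns()
    if not schema_config:
        return {c: c for c in cols}
    remap = dict(schema_config)
    out = {}
    for canonical in cols:
        out[remap.get(canonical, canonical)] = canonical
    return out


def read_cohort(
    path: str | Path,
    schema_config: Optional[Mapping[str, str]] = None,
) -> list[PatientRecord]:
    """Read a cohort CSV into :class:`PatientRecord` objects.

    Parameters
    ----------
    path:
        CSV file with one row per patient.
    schema_config:
        Optional mapping from canonical column names (``pi_t1`` ...) to
        the names actually used in the file.

    Derived fields (changes, responder label) are *not* computed here;
    see :func:`fluidresp.changes.attach_derived`.

    Raises
    ------
    SchemaError
        if an expected column is absent (the first missing one is named).
    ParseError
        if a cell is not numeric (row and column are named).
    ValidationError
        on duplicate patient ids or invariant-violating values.
    """
    path = Path(path)
    colmap = _column_map(schema_config)
    wanted = {v: k for k, v in colmap.items()}  # canonical -> file name
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canonical in default_columns():
            if wanted[canonical] not in header:
                raise SchemaError(
                    f"missing expected column {wanted[canonical]!r}")
        records: list[PatientRecord] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            pid = (row[wanted["patient_id"]] or "").strip()
            if not pid:
                raise ValidationError(f"row {i}: empty patient_id")
            if pid in seen:
                raise ValidationError(f"row {i}: duplicate patient_id {pid!r}")
            seen.add(pid)
            panels: dict[TimePoint, HemoPanel] = {}
            for tp in TimePoint:
                values: dict[str, Optional[float]] = {}
                for var in VARIABLES:
                    cell = row.get(wanted[f"{var}_{tp.key}"], "")
                    cell = (cell or "").strip()
                    if cell == "":
                        values[var] = None
                        continue
                    try:
                        values[var] = float(cell)
                    except ValueError:
                        raise ParseError(
                            f"row {i}, column {wanted[f'{var}_{tp.key}']!r}: "
                            f"non-numeric value {cell!r}") from None
                try:
                    panels[tp] = HemoPanel.from_values(values)
                except ValidationError as exc:
                    raise ValidationError(
                        f"row {i} ({pid}), {tp.name}: {exc}") from None
            records.append(PatientRecord(patient_id=pid, panels=panels))
    return records


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records to CSV; inverse of :func:`read_cohort` bit-exactly.

    Present values are formatted with ``repr`` (shortest string that
    round-trips the float); missing values are empty cells.
    """
    if not records:
        raise ValidationError("cannot write an empty cohort")
    path = Path(path)
    cols = default_columns()
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            row = [rec.patient_id]
            for var in VARIABLES:
                for tp in TimePoint:
                    v = rec.value(var, tp)
                    row.append("" if v is None else repr(float(v)))
            writer.writerow(row)


def cohort_to_dataframe(records: Sequence[PatientRecord]):
    """Wide per-patient DataFrame: measurement columns plus any derived
    change columns and the responder label."""
    import pandas as pd

    rows = []
    for rec in records:
        row: dict[str, object] = {"patient_id": rec.patient_id}
        for var in VARIABLES:
            for tp in TimePoint:
                row[f"{var}_{tp.key}"] = rec.value(var, tp)
        if rec.changes is not None:
            row.update(rec.changes.as_dict())
        row["responder"] = rec.responder
        rows.append(row)
    return pd.DataFrame(rows)
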