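"""Synthetic perioperative cohorts with the structure the analysis assumes.

The generator emulates a 32-patient elective-surgery cohort in which
~41% of patients are fluid responders.  Group-wise summary statistics
(baseline means/SDs and relative-change means/SDs for both groups) are
the published study's group summaries; the per-patient joint structure,
which the study does not report, is filled in by explicit modelling
choices:

* Every drawn quantity follows a **moment-matched truncated normal**:
  the underlying normal parameters are solved numerically so that the
  *truncated* distribution has exactly the target mean and SD.  Bounds
  keep physiology sensible (baselines > 0, LRM decreases in (-50, 100)%,
  increases of variation indices in (-90, 600)%, VE changes in
  (-90, 300)%).
* The LRM changes of perfusion index and stroke volume are correlated
  within group through a Gaussian copula (latent correlation
  ``rho_pi_sv``); all other variables are conditionally independent
  given the group, except the three arterial pressures, which share one
  latent factor per stage so that DBP <= MAP <= SBP holds jointly.
* Post-intervention panels are computed from the baselines and the drawn
  relative changes; the second baseline (T3) is the first baseline
  scaled by the published T3/T1 ratio plus a small jitter, bounded so
  the protocol's <10% baseline-return rule always holds.
* The stroke-volume VE change is drawn per group so responders land at
  >= 10% (and non-responders below) with high probability; the stored
  responder label is then *re-derived* from the realized value, so rare
  boundary crossings reassign the label.

One seeded generator drives everything; the draw order is fixed
(latent-normal matrix with a documented column layout), so a seed fully
reproduces a cohort across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .datamodel import (
    LRM_DECREASE_VARS,
    LRM_INCREASE_VARS,
    VARIABLES,
    HemoPanel,
    PatientRecord,
    TimePoint,
    ValidationError,
)
from .changes import attach_derived

__all__ = [
    "VariableEffect",
    "GroupEffectSpec",
    "CohortSpec",
    "paper_default_spec",
    "generate_cohort",
    "truncnorm_moment_params",
]

# Truncation bounds, in the units of the drawn quantity.
BASELINE_BOUNDS = (0.0, math.inf)
LRM_DECREASE_BOUNDS = (-50.0, 100.0)
LRM_INCREASE_BOUNDS = (-90.0, 600.0)
VE_CHANGE_BOUNDS = (-90.0, 300.0)
#: Hard cap on the T3-vs-T1 jitter (%); per-variable bounds may be tighter.
JITTER_CAP_PCT = 9.5

#: Variables whose T3/T4 panels are chained from T1 (the rest have no T3
#: and draw T4 directly, matching the dashes in the published table).
CHAINED_VARS = ("pi", "sv", "co", "sbp", "dbp", "map", "hr")
DIRECT_T4_VARS = ("ppv", "svv", "pvi")
PRESSURE_VARS = ("sbp", "dbp", "map")


@lru_cache(maxsize=512)
def truncnorm_moment_params(
    mean: float, sd: float, low: float, high: float
) -> tuple[float, float]:
    """Underlying ``(mu, sigma)`` of a truncated normal on ``[low, high]``
    whose truncated mean and SD equal ``mean`` and ``sd``.

    Solved by root finding on the two moment equations.  Raises
    :class:`ValidationError` when the targets are infeasible for the
    bounds (e.g. an SD larger than the interval can support).
    """
    if sd <= 0:
        raise ValidationError(f"sd must be > 0, got {sd}")
    if not (low < mean < high):
        raise ValidationError(
            f"target mean {mean} outside truncation bounds ({low}, {high})")

    def residual(p: np.ndarray) -> list[float]:
        mu, lsig = p
        sig = math.exp(min(lsig, 50.0))
        a, b = (low - mu) / sig, (high - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(residual, x0=[mean, math.log(sd)], method="hybr")
    res = residual(sol.x)
    if not sol.success or max(abs(r) for r in res) > 1e-6 * max(1.0, sd):
        raise ValidationError(
            f"cannot match mean={mean}, sd={sd} on ({low}, {high})")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float,
                   low: float, high: float) -> np.ndarray:
    mu, sig = truncnorm_moment_params(mean, sd, low, high)
    a, b = (low - mu) / sig, (high - mu) / sig
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sig)


@dataclass(frozen=True)
class VariableEffect:
    """Per-group generation targets for one hemodynamic variable.

    ``t1_mean/t1_sd`` are the first-baseline summary; ``lrm_mean/lrm_sd``
    the relative LRM change (decrease form for PI/SV/CO/pressures/HR,
    increase form for PPV/PVI/SVV).  Variables measured around VE carry
    either a ``t3_ratio`` (published T3 mean over T1 mean) plus a VE
    relative change, or a direct T4 summary (``t4_mean/t4_sd``) when no
    T3 value exists.
    """

    t1_mean: float
    t1_sd: float
    lrm_mean: float
    lrm_sd: float
    t3_ratio: Optional[float] = None
    ve_mean: Optional[float] = None
    ve_sd: Optional[float] = None
    t4_mean: Optional[float] = None
    t4_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t1_mean <= 0 or self.t1_sd < 0 or self.lrm_sd < 0:
            raise ValidationError("baseline mean must be > 0, SDs >= 0")


@dataclass(frozen=True)
class GroupEffectSpec:
    """Generation targets for both outcome groups, keyed by variable."""

    responders: dict[str, VariableEffect]
    nonresponders: dict[str, VariableEffect]

    def __post_init__(self) -> None:
        for name, group in (("responders", self.responders),
                            ("nonresponders", self.nonresponders)):
            missing = set(VARIABLES) - set(group)
            if missing:
                raise ValidationError(f"{name} missing variables: {missing}")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort.

    ``rho_pi_sv`` is the latent (copula) correlation between the LRM
    changes of PI and SV within each group; the realized Pearson
    correlation after the truncated-normal marginals is slightly
    attenuated.  ``svv_missing_nonresponders`` blanks SVV for that many
    randomly chosen non-responders, mimicking the published table's
    smaller SVV denominator.
    """

    n_patients: int
    effects: GroupEffectSpec
    responder_fraction: float = 0.406
    rho_pi_sv: float = 0.35
    seed: int = 0
    baseline_jitter_sd_pct: float = 3.0
    svv_missing_nonresponders: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValidationError("responder_fraction must be in (0, 1)")
        if not abs(self.rho_pi_sv) < 1.0:
            raise ValidationError("|rho_pi_sv| must be < 1")
        if self.baseline_jitter_sd_pct < 0:
            raise ValidationError("baseline_jitter_sd_pct must be >= 0")
        if not 0 <= self.svv_missing_nonresponders <= self.n_patients:
            raise ValidationError("svv_missing_nonresponders out of range")


def paper_default_spec(n_patients: int = 32, seed: int = 0) -> CohortSpec:
    """The published study's conditions: 32 patients, 40.6% responders,
    group summaries from the printed baseline and change tables.

    VE-change means for each variable are derived from the printed
    before/after VE group means (e.g. responders' stroke volume
    59.8 -> 73.0 mL gives +22.07%); their SDs, and the SVV LRM-change
    summary, are not printed and are fixed modelling choices (see the
    methods note).
    """

    def eff(t1, lrm, t3=None, ve=None, t4=None) -> VariableEffect:
        kw: dict = {"t1_mean": t1[0], "t1_sd": t1[1],
                    "lrm_mean": lrm[0], "lrm_sd": lrm[1]}
        if t3 is not None:
            kw["t3_ratio"] = t3
        if ve is not None:
            kw["ve_mean"], kw["ve_sd"] = ve
        if t4 is not None:
            kw["t4_mean"], kw["t4_sd"] = t4
        return VariableEffect(**kw)

    def ratio_change(before: float, after: float) -> float:
        return (after - before) / before * 100.0

    responders = {
        "pi": eff((2.30, 1.98), (55.23, 17.82), t3=2.25 / 2.30,
                  ve=(ratio_change(2.25, 2.52), 15.0)),
        "sv": eff((60.3, 25.4), (49.42, 21.49), t3=59.8 / 60.3,
                  ve=(ratio_change(59.8, 73.0), 6.0)),
        "co": eff((4.28, 1.30), (58.92, 18.70), t3=4.25 / 4.28,
                  ve=(ratio_change(4.25, 5.05), 8.0)),
        "sbp": eff((113.0, 18.0), (30.42, 11.56), t3=108.0 / 113.0,
                   ve=(ratio_change(108.0, 116.0), 8.0)),
        "dbp": eff((64.0, 17.0), (19.12, 10.59), t3=63.0 / 64.0,
                   ve=(0.0, 8.0)),
        "map": eff((82.0, 16.0), (26.27, 10.93), t3=80.0 / 82.0,
                   ve=(ratio_change(80.0, 83.0), 6.0)),
        "hr": eff((75.0, 17.0), (5.08, 8.93), t3=1.0,
                  ve=(ratio_change(75.0, 73.0), 5.0)),
        "ppv": eff((18.85, 7.55), (58.1, 84.8), t4=(12.0, 8.2)),
        "svv": eff((25.91, 12.56), (ratio_change(25.2, 43.3), 50.0),
                   t4=(18.4, 8.0)),
        "pvi": eff((13.92, 4.77), (45.3, 10.0), t4=(9.7, 3.2)),
    }
    nonresponders = {
        "pi": eff((2.35, 2.08), (35.32, 17.32), t3=2.41 / 2.35,
                  ve=(ratio_change(2.41, 2.08), 15.0)),
        "sv": eff((77.7, 21.4), (39.79, 21.44), t3=75.9 / 77.7,
                  ve=(ratio_change(75.9, 76.1), 4.0)),
        "co": eff((5.13, 1.69), (47.39, 22.87), t3=4.83 / 5.13,
                  ve=(ratio_change(4.83, 4.95), 5.0)),
        "sbp": eff((114.0, 18.0), (20.22, 10.50), t3=107.0 / 114.0,
                   ve=(ratio_change(107.0, 122.0), 8.0)),
        "dbp": eff((61.0, 8.0), (14.55, 8.99), t3=58.0 / 61.0,
                   ve=(ratio_change(58.0, 66.0), 8.0)),
        "map": eff((81.0, 13.0), (19.47, 9.61), t3=77.0 / 81.0,
                   ve=(ratio_change(77.0, 88.0), 8.0)),
        "hr": eff((67.0, 14.0), (7.12, 7.50), t3=64.0 / 67.0,
                  ve=(ratio_change(64.0, 65.0), 5.0)),
        "ppv": eff((9.53, 6.00), (95.9, 102.5), t4=(6.0, 3.5)),
        "svv": eff((17.88, 6.28), (ratio_change(17.9, 27.3), 40.0),
                   t4=(18.8, 12.2)),
        "pvi": eff((12.00, 6.82), (35.9, 6.4), t4=(12.6, 6.5)),
    }
    return CohortSpec(
        n_patients=n_patients,
        effects=GroupEffectSpec(responders, nonresponders),
        seed=seed,
    )


# Latent-normal column layout (fixed; reproducibility contract).
# T1 baselines: pi, sv, co, hr, pressures-shared, ppv, svv, pvi
# LRM changes:  pi, sv-residual, co, hr, pressures-shared, ppv, pvi, svv
# T3 jitter:    pi, sv, co, hr, pressures-shared
# VE changes:   pi, sv, co, hr, pressures-shared
# T4 direct:    ppv, svv, pvi
_N_LATENT = 29
_COL = {}
_i = 0
for _name in ("t1_pi", "t1_sv", "t1_co", "t1_hr", "t1_press",
              "t1_ppv", "t1_svv", "t1_pvi",
              "lrm_pi", "lrm_sv_res", "lrm_co", "lrm_hr", "lrm_press",
              "lrm_ppv", "lrm_pvi", "lrm_svv",
              "j_pi", "j_sv", "j_co", "j_hr", "j_press",
              "ve_pi", "ve_sv", "ve_co", "ve_hr", "ve_press",
              "t4_ppv", "t4_svv", "t4_pvi"):
    _COL[_name] = _i
    _i += 1
assert _i == _N_LATENT


def _lrm_bounds(var: str) -> tuple[float, float]:
    return (LRM_INCREASE_BOUNDS if var in LRM_INCREASE_VARS
            else LRM_DECREASE_BOUNDS)


def _jitter_bounds(ratio: float, cap: float = JITTER_CAP_PCT) -> tuple[float, float]:
    # combined deviation ratio*(1+j/100) must stay strictly inside +-10%
    lo = max(-cap, (0.905 / ratio - 1.0) * 100.0)
    hi = min(cap, (1.095 / ratio - 1.0) * 100.0)
    return lo, hi


def generate_cohort(
    spec: CohortSpec,
    return_draws: bool = False,
) -> list[PatientRecord] | tuple[list[PatientRecord], "object"]:
    """Generate one cohort; deterministic given ``spec.seed``.

    With ``return_draws=True`` additionally returns a DataFrame of the
    raw drawn quantities (including the *drawn* group, before any
    boundary reassignment of the responder label), which is what
    calibration checks should compare against the spec's targets.
    """
    import pandas as pd

    n = spec.n_patients
    rng = np.random.default_rng(spec.seed)
    is_resp = rng.random(n) < spec.responder_fraction
    z = rng.standard_normal((n, _N_LATENT))

    # correlate the PI and SV LRM changes through the latent pair
    rho = spec.rho_pi_sv
    z_sv = rho * z[:, _COL["lrm_pi"]] + math.sqrt(1 - rho * rho) * z[:, _COL["lrm_sv_res"]]

    def zcol(name: str) -> np.ndarray:
        return z_sv if name == "lrm_sv" else z[:, _COL[name]]

    def draw(zname: str, key: str, mean_sd, bounds) -> np.ndarray:
        """Group-wise copula transform of one latent column."""
        u = stats.norm.cdf(zcol(zname))
        out = np.empty(n)
        for mask, group in ((is_resp, spec.effects.responders),
                            (~is_resp, spec.effects.nonresponders)):
            if not mask.any():
                continue
            eff = group[key]
            m, s = mean_sd(eff)
            out[mask] = _truncnorm_ppf(u[mask], m, s, *bounds)
        return out

    t1: dict[str, np.ndarray] = {}
    lrm: dict[str, np.ndarray] = {}
    for var in VARIABLES:
        zb = "t1_press" if var in PRESSURE_VARS else f"t1_{var}"
        t1[var] = draw(zb, var, lambda e: (e.t1_mean, e.t1_sd), BASELINE_BOUNDS)
        zl = "lrm_press" if var in PRESSURE_VARS else f"lrm_{var}"
        lrm[var] = draw(zl, var, lambda e: (e.lrm_mean, e.lrm_sd), _lrm_bounds(var))

    t2: dict[str, np.ndarray] = {}
    for var in VARIABLES:
        sign = -1.0 if var in LRM_DECREASE_VARS else 1.0
        t2[var] = t1[var] * (1.0 + sign * lrm[var] / 100.0)

    t3: dict[str, Optional[np.ndarray]] = {v: None for v in VARIABLES}
    t4: dict[str, np.ndarray] = {}
    ve: dict[str, np.ndarray] = {}
    for var in CHAINED_VARS:
        zj = "j_press" if var in PRESSURE_VARS else f"j_{var}"
        u = stats.norm.cdf(zcol(zj))
        arr = np.empty(n)
        for mask, group in ((is_resp, spec.effects.responders),
                            (~is_resp, spec.effects.nonresponders)):
            if not mask.any():
                continue
            eff = group[var]
            ratio = eff.t3_ratio if eff.t3_ratio is not None else 1.0
            lo, hi = _jitter_bounds(ratio)
            jit = (_truncnorm_ppf(u[mask], 0.0, spec.baseline_jitter_sd_pct, lo, hi)
                   if spec.baseline_jitter_sd_pct > 0 else np.zeros(mask.sum()))
            arr[mask] = t1[var][mask] * ratio * (1.0 + jit / 100.0)
        t3[var] = arr
        zv = "ve_press" if var in PRESSURE_VARS else f"ve_{var}"
        ve[var] = draw(zv, var,
                       lambda e: (e.ve_mean, e.ve_sd), VE_CHANGE_BOUNDS)
        t4[var] = arr * (1.0 + ve[var] / 100.0)
    for var in DIRECT_T4_VARS:
        t4[var] = draw(f"t4_{var}", var,
                       lambda e: (e.t4_mean, e.t4_sd), BASELINE_BOUNDS)

    # Residual pressure-ordering repair: the shared latent factor makes
    # DBP <= MAP <= SBP hold essentially always; clip MAP for the rare
    # extreme-tail exception so every panel validates.
    for stage in (t1, t2, t3, t4):
        s, d, m = stage.get("sbp"), stage.get("dbp"), stage.get("map")
        if s is None or d is None or m is None:
            continue
        np.clip(m, d, s, out=m)

    svv_blank = np.zeros(n, dtype=bool)
    if spec.svv_missing_nonresponders:
        nonresp_idx = np.flatnonzero(ve["sv"] < 10.0)
        k = min(spec.svv_missing_nonresponders, nonresp_idx.size)
        if k:
            svv_blank[rng.choice(nonresp_idx, size=k, replace=False)] = True

    width = len(str(n))
    records: list[PatientRecord] = []
    stage_by_tp = {TimePoint.T1: t1, TimePoint.T2: t2,
                   TimePoint.T3: t3, TimePoint.T4: t4}
    for i in range(n):
        panels = {}
        for tp, stage in stage_by_tp.items():
            values = {}
            for var in VARIABLES:
                arr = stage.get(var)
                if arr is None or (svv_blank[i] and var == "svv"):
                    values[var] = None
                else:
                    values[var] = float(arr[i])
            panels[tp] = HemoPanel.from_values(values)
        records.append(PatientRecord(patient_id=f"P{i + 1:0{width}d}",
                                     panels=panels))
    attach_derived(records)

    if not return_draws:
        return records
    draws = {"patient_id": [r.patient_id for r in records],
             "drawn_group": np.where(is_resp, "responder", "nonresponder")}
    for var in VARIABLES:
        draws[f"t1_{var}"] = t1[var]
        draws[f"lrm_{var}"] = lrm[var]
    for var in CHAINED_VARS:
        draws[f"ve_{var}"] = ve[var]
    for var in DIRECT_T4_VARS:
        draws[f"t4_{var}"] = t4[var]
    return records, pd.DataFrame(draws)
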