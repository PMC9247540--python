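"""Study-level model and results objects.

:class:`FluidResponsivenessStudy` is built from a cohort (a CSV file, a
wide DataFrame, patient records, or a simulation spec) and carries an
:class:`AnalysisConfig`.  Its :meth:`~FluidResponsivenessStudy.fit`
derives per-patient relative changes and responder labels, then runs
the full diagnostic evaluation and returns a
:class:`FluidResponsivenessResults` holding:

* a per-patient changes table,
* before/after comparisons per group and intervention,
* a per-marker table (group mean +- SD, AUC with DeLong 95% CI, the
  Youden-optimal cutoff),
* the full diagnostic-metric block (Sn/Sp/PPV/NPV/LR with exact and
  log-method CIs) at the primary marker's cutoff,
* the combined gray zone with the below/inside/above cohort split,
* correlation and four-quadrant concordance of the PI and SV changes,
* an echo of the ROC sample-size calculation.

Every stochastic stage is driven by the config seed; refitting with the
same data and config is byte-identical (including the JSON export).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import roc as _roc
from .changes import attach_derived, relative_increase
from .cohort import CohortSpec, generate_cohort, paper_default_spec
from .datamodel import (
    PatientRecord,
    TimePoint,
    VARIABLES,
    cohort_to_dataframe,
    read_cohort,
)
from .diagnostics import (
    DiagnosticSummary,
    classify_at_cutoff,
    diagnostic_summary,
)
from .grayzone import GrayZone, GrayZoneSettings, combined_zone
from .roc import (
    CutoffResult,
    DegenerateLabelsError,
    RocResult,
    VarianceUndefinedError,
    delong_paired_test,
    empirical_roc,
    youden_best_cutoff,
)
from .samplesize import (
    RocSampleSizeSpec,
    SampleSizeResult,
    inflate_for_dropout,
    obuchowski_n,
)
from .trending import (
    ComparisonResult,
    ConcordanceResult,
    compare_groups,
    compare_paired,
    four_quadrant_concordance,
    format_p,
    linear_r2,
)

__all__ = ["AnalysisConfig", "FluidResponsivenessStudy",
           "FluidResponsivenessResults"]

log = logging.getLogger("fluidresp")

#: Markers evaluated by default: LRM relative decreases plus the
#: baseline respiratory-variation indices.  All are oriented so that a
#: larger value argues for fluid responsiveness.
DEFAULT_MARKERS: tuple[str, ...] = (
    "delta_pi_lrm", "delta_sv_lrm", "delta_co_lrm", "delta_sbp_lrm",
    "delta_dbp_lrm", "delta_map_lrm", "delta_hr_lrm",
    "ppv_t1", "svv_t1", "pvi_t1",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the pipeline needs beyond the cohort itself."""

    markers: tuple[str, ...] = DEFAULT_MARKERS
    primary_marker: str = "delta_pi_lrm"
    comparison_marker: Optional[str] = "ppv_t1"
    responder_threshold: float = 10.0
    fixed_cutoff: Optional[float] = None  # None -> Youden-optimal
    level: float = 0.95
    n_boot: int = 1000
    seed: int = 0
    sn_floor: float = 0.90
    sp_floor: float = 0.90
    stratified_bootstrap: bool = False
    concordance_exclusion_pct: float = 10.0
    sample_size: RocSampleSizeSpec = field(default_factory=lambda: RocSampleSizeSpec(
        auc_alt=0.80, auc_null=0.50, ratio_neg_pos=1.222,
        alpha=0.05, power=0.90, sided="one"))
    dropout: float = 0.15

    def __post_init__(self) -> None:
        if self.primary_marker not in self.markers:
            raise ValueError("primary_marker must be one of markers")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        if "sample_size" in raw:
            raw["sample_size"] = RocSampleSizeSpec(**raw["sample_size"])
        if "markers" in raw:
            raw["markers"] = tuple(raw["markers"])
        return cls(**raw)


def _marker_values(df: pd.DataFrame, name: str) -> np.ndarray:
    """Marker column from the wide changes table; ``<var>_t1`` names pull
    the raw baseline measurement."""
    if name not in df.columns:
        raise KeyError(f"unknown marker {name!r}")
    return df[name].to_numpy(dtype=float)


class FluidResponsivenessStudy:
    """Diagnostic-evaluation model for a perioperative cohort."""

    def __init__(self, records: Sequence[PatientRecord],
                 config: Optional[AnalysisConfig] = None):
        if not records:
            raise ValueError("empty cohort")
        self.records = list(records)
        self.config = config or AnalysisConfig()

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path,
                 schema_config: Optional[Mapping[str, str]] = None,
                 config: Optional[AnalysisConfig] = None
                 ) -> "FluidResponsivenessStudy":
        return cls(read_cohort(path, schema_config), config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: Optional[AnalysisConfig] = None
                       ) -> "FluidResponsivenessStudy":
        """Build from a wide table with ``patient_id`` and ``<var>_<tp>``
        columns (the CSV schema as a DataFrame)."""
        from .datamodel import HemoPanel

        records = []
        for _, row in df.iterrows():
            panels = {}
            for tp in TimePoint:
                values = {}
                for var in VARIABLES:
                    col = f"{var}_{tp.key}"
                    v = row.get(col)
                    values[var] = None if v is None or pd.isna(v) else float(v)
                panels[tp] = HemoPanel.from_values(values)
            records.append(PatientRecord(patient_id=str(row["patient_id"]),
                                         panels=panels))
        return cls(records, config)

    @classmethod
    def simulate(cls, spec: Optional[CohortSpec] = None,
                 n_patients: int = 32, seed: int = 0,
                 config: Optional[AnalysisConfig] = None
                 ) -> "FluidResponsivenessStudy":
        """A synthetic cohort under the published study's conditions."""
        if spec is None:
            spec = paper_default_spec(n_patients=n_patients, seed=seed)
        return cls(generate_cohort(spec), config)

    # ---- fitting ------------------------------------------------------
    def fit(self) -> "FluidResponsivenessResults":
        cfg = self.config
        attach_derived(self.records, cfg.responder_threshold)
        df = cohort_to_dataframe(self.records)
        labels = df["responder"].to_numpy()
        usable = pd.notna(labels)
        if usable.sum() < len(df):
            log.info("stage=labels n=%d dropped_unlabelled=%d",
                     len(df), int(len(df) - usable.sum()))
        df = df.loc[usable].reset_index(drop=True)
        y = df["responder"].to_numpy(dtype=bool)
        log.info("stage=cohort n=%d responders=%d seed=%d",
                 len(df), int(y.sum()), cfg.seed)

        warnings_log: list[str] = []
        marker_rows = []
        rocs: dict[str, Optional[RocResult]] = {}
        cutoffs: dict[str, Optional[CutoffResult]] = {}
        for name in cfg.markers:
            s = _marker_values(df, name)
            try:
                r = empirical_roc(s, y, level=cfg.level)
            except DegenerateLabelsError as exc:
                warnings_log.append(f"roc[{name}]: {exc}")
                rocs[name] = None
                cutoffs[name] = None
                continue
            rocs[name] = r
            if r.auc_ci is None:
                warnings_log.append(
                    f"roc[{name}]: DeLong variance undefined "
                    "(fewer than 2 observations in a class)")
            cutoffs[name] = youden_best_cutoff(s, y)
            sv = s[np.isfinite(s)]
            yv = y[np.isfinite(s)]
            marker_rows.append({
                "marker": name,
                "mean_responders": float(np.mean(sv[yv])) if yv.any() else np.nan,
                "sd_responders": float(np.std(sv[yv], ddof=1)) if yv.sum() > 1 else np.nan,
                "mean_nonresponders": float(np.mean(sv[~yv])) if (~yv).any() else np.nan,
                "sd_nonresponders": float(np.std(sv[~yv], ddof=1)) if (~yv).sum() > 1 else np.nan,
                "auc": r.auc,
                "auc_ci_low": r.auc_ci[0] if r.auc_ci else np.nan,
                "auc_ci_high": r.auc_ci[1] if r.auc_ci else np.nan,
                "n_pos": r.n_pos, "n_neg": r.n_neg,
            })
        marker_table = pd.DataFrame(marker_rows).set_index("marker")

        # primary-marker cutoff block, gray zone
        primary = cfg.primary_marker
        s = _marker_values(df, primary)
        diagnostics: Optional[DiagnosticSummary] = None
        gray: Optional[GrayZone] = None
        cutoff_used: Optional[float] = None
        if rocs.get(primary) is not None:
            cutoff_used = (cfg.fixed_cutoff if cfg.fixed_cutoff is not None
                           else cutoffs[primary].cutoff)
            diagnostics = diagnostic_summary(
                classify_at_cutoff(s, y, cutoff_used), cfg.level)
            try:
                gray = combined_zone(
                    s, y, GrayZoneSettings(
                        n_boot=cfg.n_boot, level=cfg.level, seed=cfg.seed,
                        sn_floor=cfg.sn_floor, sp_floor=cfg.sp_floor,
                        stratified=cfg.stratified_bootstrap))
                log.info("stage=grayzone n_boot=%d seed=%d redrawn=%d",
                         cfg.n_boot, cfg.seed, gray.redrawn_replicates)
            except (DegenerateLabelsError, ValueError) as exc:
                warnings_log.append(f"grayzone: {exc}")

        # paired AUC comparison of the primary marker vs the comparator
        auc_comparison = None
        if cfg.comparison_marker and rocs.get(primary) is not None:
            try:
                auc_comparison = delong_paired_test(
                    _marker_values(df, primary),
                    _marker_values(df, cfg.comparison_marker), y)
            except (DegenerateLabelsError, VarianceUndefinedError) as exc:
                warnings_log.append(f"auc_comparison: {exc}")

        # before/after comparisons per group and intervention
        comparisons = self._group_time_comparisons(df, y, warnings_log)

        # correlation and trending concordance of PI vs SV changes
        correlations: dict[str, tuple[float, float]] = {}
        concordance: Optional[ConcordanceResult] = None
        try:
            correlations["delta_pi_lrm~delta_sv_lrm"] = linear_r2(
                df["delta_pi_lrm"], df["delta_sv_lrm"])
            correlations["delta_pi_lrm~delta_sv_ve"] = linear_r2(
                df["delta_pi_lrm"], df["delta_sv_ve"])
        except ValueError as exc:
            warnings_log.append(f"correlation: {exc}")
        try:
            concordance = self._pi_sv_concordance(df)
        except ValueError as exc:
            warnings_log.append(f"concordance: {exc}")

        n_required = obuchowski_n(cfg.sample_size)
        n_planned = inflate_for_dropout(n_required.n_total, cfg.dropout)

        return FluidResponsivenessResults(
            study=self, data=df, labels=y, marker_table=marker_table,
            rocs=rocs, cutoffs=cutoffs, cutoff_used=cutoff_used,
            diagnostics=diagnostics, gray_zone=gray,
            auc_comparison=auc_comparison, comparisons=comparisons,
            correlations=correlations, concordance=concordance,
            sample_size=n_required, n_planned=n_planned,
            warnings=warnings_log)

    def _group_time_comparisons(self, df: pd.DataFrame, y: np.ndarray,
                                warnings_log: list[str]) -> pd.DataFrame:
        rows = []
        pairs = [("lrm", "t1", "t2"), ("ve", "t3", "t4")]
        for grp_name, mask in (("responders", y), ("nonresponders", ~y)):
            for var in VARIABLES:
                for intervention, a, b in pairs:
                    before = df.loc[mask, f"{var}_{a}"].to_numpy(dtype=float)
                    after = df.loc[mask, f"{var}_{b}"].to_numpy(dtype=float)
                    keep = np.isfinite(before) & np.isfinite(after)
                    if keep.sum() < 3:
                        continue
                    try:
                        res = compare_paired(before[keep], after[keep])
                    except ValueError as exc:
                        warnings_log.append(
                            f"compare[{grp_name},{var},{intervention}]: {exc}")
                        continue
                    rows.append({
                        "group": grp_name, "variable": var,
                        "intervention": intervention,
                        "n": int(keep.sum()),
                        "mean_before": float(np.mean(before[keep])),
                        "sd_before": float(np.std(before[keep], ddof=1)),
                        "mean_after": float(np.mean(after[keep])),
                        "sd_after": float(np.std(after[keep], ddof=1)),
                        "p": res.p, "test": res.test_used,
                    })
        # between-group comparison of each marker
        return pd.DataFrame(rows)

    def _pi_sv_concordance(self, df: pd.DataFrame) -> ConcordanceResult:
        """Stacked (PI change, SV change) pairs over both interventions,
        oriented as signed increases."""
        cfg = self.config
        dpi_lrm = -df["delta_pi_lrm"].to_numpy(dtype=float)  # to increase form
        dsv_lrm = -df["delta_sv_lrm"].to_numpy(dtype=float)
        pi_t3 = df["pi_t3"].to_numpy(dtype=float)
        pi_t4 = df["pi_t4"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            dpi_ve = (pi_t4 - pi_t3) / pi_t3 * 100.0
        dsv_ve = df["delta_sv_ve"].to_numpy(dtype=float)
        dx = np.concatenate([dpi_lrm, dpi_ve])
        dy = np.concatenate([dsv_lrm, dsv_ve])
        return four_quadrant_concordance(
            dx, dy, exclusion=cfg.concordance_exclusion_pct)


@dataclass
class FluidResponsivenessResults:
    """Fitted diagnostic evaluation; see the module docstring."""

    study: FluidResponsivenessStudy
    data: pd.DataFrame
    labels: np.ndarray
    marker_table: pd.DataFrame
    rocs: dict[str, Optional[RocResult]]
    cutoffs: dict[str, Optional[CutoffResult]]
    cutoff_used: Optional[float]
    diagnostics: Optional[DiagnosticSummary]
    gray_zone: Optional[GrayZone]
    auc_comparison: Optional[tuple[float, float, float, float]]
    comparisons: pd.DataFrame
    correlations: dict[str, tuple[float, float]]
    concordance: Optional[ConcordanceResult]
    sample_size: SampleSizeResult
    n_planned: int
    warnings: list[str]

    # ---- exports ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_responders(self) -> int:
        return int(self.labels.sum())

    def to_dict(self) -> dict:
        cfg = self.study.config

        def _zone(z: Optional[GrayZone]):
            if z is None:
                return None
            return {"lower": z.lower, "upper": z.upper, "method": z.method,
                    "fractions": {"below": z.fractions[0],
                                  "inside": z.fractions[1],
                                  "above": z.fractions[2]}}

        out: dict = {
            "n": self.n,
            "n_responders": self.n_responders,
            "prevalence": self.n_responders / self.n,
            "seed": cfg.seed,
            "markers": {},
            "primary_marker": cfg.primary_marker,
            "cutoff_used": self.cutoff_used,
            "sample_size": {"n_pos": self.sample_size.n_pos,
                            "n_neg": self.sample_size.n_neg,
                            "n_total": self.sample_size.n_total,
                            "n_planned": self.n_planned},
            "warnings": list(self.warnings),
        }
        for name, r in self.rocs.items():
            cut = self.cutoffs.get(name)
            out["markers"][name] = None if r is None else {
                "auc": r.auc,
                "auc_ci": list(r.auc_ci) if r.auc_ci else None,
                "youden_cutoff": cut.cutoff if cut else None,
                "youden_j": cut.youden_j if cut else None,
            }
        if self.diagnostics is not None:
            d = self.diagnostics
            out["diagnostics"] = {
                "table": {"tp": d.table.tp, "fn": d.table.fn,
                          "fp": d.table.fp, "tn": d.table.tn},
                **{k: {"estimate": m.estimate, "ci": list(m.ci),
                       "method": m.method}
                   for k, m in (("sensitivity", d.sens), ("specificity", d.spec),
                                ("ppv", d.ppv), ("npv", d.npv),
                                ("lr_pos", d.lr_pos), ("lr_neg", d.lr_neg))},
            }
        out["gray_zone"] = _zone(self.gray_zone)
        if self.gray_zone is not None:
            out["gray_zone"]["bootstrap"] = _zone(self.gray_zone.bootstrap_zone)
            out["gray_zone"]["triadic"] = _zone(self.gray_zone.triadic_zone)
        if self.auc_comparison is not None:
            a, b, z, p = self.auc_comparison
            out["auc_comparison"] = {
                "marker_a": cfg.primary_marker, "auc_a": a,
                "marker_b": cfg.comparison_marker, "auc_b": b,
                "z": z, "p": p}
        out["correlations"] = {k: {"r2": v[0], "p": v[1]}
                               for k, v in self.correlations.items()}
        if self.concordance is not None:
            c = self.concordance
            out["concordance"] = {"rate": c.rate, "n_used": c.n_used,
                                  "n_total": c.n_total,
                                  "exclusion_pct": c.exclusion_pct}
        return out

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        """Human-readable report."""
        cfg = self.study.config
        lines = []
        lines.append("Fluid-responsiveness diagnostic evaluation")
        lines.append("=" * 58)
        lines.append(f"Patients: {self.n}  responders: {self.n_responders} "
                     f"({self.n_responders / self.n * 100:.1f}%)")
        lines.append("")
        lines.append("Markers (group mean +- SD, AUC with 95% CI):")
        for name, row in self.marker_table.iterrows():
            ci = ("-" if np.isnan(row.auc_ci_low)
                  else f"{row.auc_ci_low:.2f}-{row.auc_ci_high:.2f}")
            lines.append(
                f"  {name:<16} R {row.mean_responders:7.2f} +- {row.sd_responders:6.2f}"
                f"  NR {row.mean_nonresponders:7.2f} +- {row.sd_nonresponders:6.2f}"
                f"  AUC {row.auc:.2f} ({ci})")
        if self.cutoff_used is not None and self.diagnostics is not None:
            lines.append("")
            lines.append(f"Primary marker {cfg.primary_marker} at cutoff >= "
                         f"{self.cutoff_used:.2f}:")
            for key, val in self.diagnostics.formatted().items():
                lines.append(f"  {key:<12} {val}")
        if self.auc_comparison is not None:
            a, b, z, p = self.auc_comparison
            lines.append(f"  AUC vs {cfg.comparison_marker}: "
                         f"{a:.2f} vs {b:.2f}, p = {format_p(p)}")
        if self.gray_zone is not None:
            z = self.gray_zone
            lines.append("")
            lines.append(
                f"Gray zone ({z.method}): {z.lower:.1f} to {z.upper:.1f} %")
            lines.append(
                f"  below {z.fractions[0] * 100:.1f}%  "
                f"inconclusive {z.fractions[1] * 100:.1f}%  "
                f"above {z.fractions[2] * 100:.1f}%")
        if self.correlations:
            lines.append("")
            for k, (r2, p) in self.correlations.items():
                lines.append(f"  {k}: r2 = {r2:.2f}, p = {format_p(p)}")
        if self.concordance is not None:
            c = self.concordance
            lines.append(f"  concordance rate = {c.rate:.2f}% "
                         f"({c.n_used}/{c.n_total} pairs, "
                         f"{c.exclusion_pct:.0f}% exclusion zone)")
        lines.append("")
        lines.append(
            f"Sample size (AUC {cfg.sample_size.auc_alt} vs "
            f"{cfg.sample_size.auc_null}, R = {cfg.sample_size.ratio_neg_pos}, "
            f"alpha = {cfg.sample_size.alpha}, power = {cfg.sample_size.power}): "
            f"{self.sample_size.n_total} patients; "
            f"{self.n_planned} planned at {cfg.dropout * 100:.0f}% dropout")
        if self.warnings:
            lines.append("")
            lines.append("Warnings:")
            for w in self.warnings:
                lines.append(f"  - {w}")
        return "\n".join(lines)
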