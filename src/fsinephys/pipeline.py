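"""End-to-end orchestration: dataset -> per-cell summaries -> paired statistics.

A run is fully described by a :class:`RunConfig` (serializable to YAML); its
effective configuration is archived next to the outputs together with the
seed and package version, and reruns with the same config and seed produce
byte-identical report tables.  Partial failures isolate the failing cell:
the error is logged with a reason code and the rest of the cohort proceeds.
No sweep, spike, event or cell is dropped silently — every exclusion appears
in the QC log.

Units are mV, pA, ms, MOhm and Hz throughout; adapters for other container
formats must convert at the boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import load_cohort
from .epsc_analysis import (
    SERIES_RESISTANCE_CAP_MOHM,
    AmplitudeConfig,
    potentiation,
    qc_series_resistance,
)
from .fi_analysis import (
    ClassificationConfig,
    build_fi_curve,
    classify_cell,
    fit_fi_sigmoid,
    rheobase,
    select_rheobase_plus,
    threshold_from_ramp,
)
from .passive_props import (
    average_sweeps,
    input_resistance_cc,
    input_resistance_vc,
    membrane_tau,
    resting_potential,
)
from .stats_compare import PairedComparison, paired_t, rm_anova_treatment, wilcoxon_signed_rank
from .synthetic_data import GroundTruthManifest
from .trace_features import (
    DetectionConfig,
    FeatureConfig,
    adaptation_ratio,
    extract_ap_features,
)

logger = logging.getLogger("fsinephys")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "recovery_check", "write_report"]

CONDITIONS = ("baseline", "drug")

#: measures compared with the Wilcoxon signed-rank test rather than paired t
#: (skewed fit parameters of the F-I sigmoid)
WILCOXON_MEASURES = ("xhalf", "rising_rate")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable for provenance."""

    input_dir: str = ""
    output_dir: str = ""
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    epsc_amplitude: AmplitudeConfig = field(default_factory=AmplitudeConfig)
    rs_cap_mohm: float = SERIES_RESISTANCE_CAP_MOHM
    rheobase_plus_offset_pa: float = 50.0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        for key, typ in (
            ("detection", DetectionConfig),
            ("features", FeatureConfig),
            ("classification", ClassificationConfig),
            ("epsc_amplitude", AmplitudeConfig),
        ):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = typ(**doc[key])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    """All tables produced by one pipeline run."""

    cell_summary: pd.DataFrame        # one row per cell per condition
    ap_features: pd.DataFrame         # one row per measured AP
    comparisons: pd.DataFrame         # one row per paired test
    epsc_timecourse: pd.DataFrame     # per-event amplitudes
    qc_log: list[dict]
    provenance: dict


def _qc(qc_log: list[dict], cell: str, code: str, detail: str) -> None:
    qc_log.append({"cell": cell, "code": code, "detail": detail})
    logger.info("QC [%s] %s: %s", cell, code, detail)


def _analyze_condition(
    cell_id: str,
    cond: str,
    by_label: dict,
    config: RunConfig,
    qc_log: list[dict],
    ap_rows: list[dict],
) -> dict:
    """Per-cell per-condition summary row; missing protocols leave NaNs."""
    row: dict = {"cell": cell_id, "condition": cond}

    rmp_sweeps = by_label.get("subthreshold") or by_label.get("characterization")
    if rmp_sweeps:
        vals = []
        for s in rmp_sweeps:
            try:
                vals.append(resting_potential(s, config.detection))
            except ValueError as err:
                _qc(qc_log, cell_id, "rmp_window", f"{cond}: {err}")
        if vals:
            row["rmp"] = float(np.mean(vals))

    if "subthreshold" in by_label:
        try:
            rin, diag = input_resistance_cc(by_label["subthreshold"], config.detection)
            row["rin_cc"] = rin
            row["vi_r_squared"] = diag["r_squared"]
            if diag["excluded_amplitudes"]:
                _qc(
                    qc_log, cell_id, "vi_spiking_sweeps",
                    f"{cond}: excluded amplitudes {diag['excluded_amplitudes']}",
                )
        except ValueError as err:
            _qc(qc_log, cell_id, "rin_cc_failed", f"{cond}: {err}")

    if "vclamp" in by_label:
        try:
            row["rin_vc"] = input_resistance_vc(by_label["vclamp"][0])
        except ValueError as err:
            _qc(qc_log, cell_id, "rin_vc_failed", f"{cond}: {err}")

    if "brief_pulse" in by_label:
        try:
            fit = membrane_tau(average_sweeps(by_label["brief_pulse"]))
            row["tau"] = fit.tau_slow
            row["tau_fast"] = fit.tau_fast
            row["tau_r_squared"] = fit.r_squared
            for flag in fit.qc_flags:
                _qc(qc_log, cell_id, "tau_fit_qc", f"{cond}: {flag}")
        except (ValueError, RuntimeError) as err:
            _qc(qc_log, cell_id, "tau_fit_failed", f"{cond}: {err}")

    curve = None
    if "fi" in by_label:
        curve = build_fi_curve(by_label["fi"], config.detection)
        row["max_rate"] = curve.max_rate
        try:
            fit = fit_fi_sigmoid(curve)
            row.update(
                fi_max_rate=fit.max_rate, xhalf=fit.xhalf, fi_k=fit.k,
                rising_rate=fit.rising_rate, fi_r_squared=fit.r_squared,
            )
        except (ValueError, RuntimeError) as err:
            _qc(qc_log, cell_id, "fi_fit_failed", f"{cond}: {err}")

    rheo_sweeps = by_label.get("rheobase_fine") or by_label.get("fi")
    rheo = None
    if rheo_sweeps:
        rheo = rheobase(rheo_sweeps, config.detection)
        if rheo.defined:
            row["rheobase"] = rheo.current_pa
            row["rheobase_resolution"] = rheo.resolution_pa
            if rheo.unbounded_below:
                _qc(
                    qc_log, cell_id, "rheobase_unbounded",
                    f"{cond}: all sweeps spiked; rheobase is an upper bound",
                )
        else:
            _qc(qc_log, cell_id, "rheobase_undefined", f"{cond}: no sweep spiked")

    ap_source = by_label.get("fi") or by_label.get("characterization")
    if ap_source and rheo is not None and rheo.defined:
        try:
            sweep = select_rheobase_plus(
                ap_source, rheo.current_pa, config.rheobase_plus_offset_pa
            )
            feats = extract_ap_features(sweep, config.detection, config.features)
            if feats:
                spike_times = [f.peak_time for f in feats]
                row["adaptation_ratio"] = adaptation_ratio(spike_times) if len(feats) >= 3 else float("nan")
                for k, f in enumerate(feats):
                    ap_rows.append(
                        {
                            "cell": cell_id, "condition": cond,
                            "sweep_amplitude": sweep.stimulus.amplitude,
                            "spike_index": k, "threshold": f.threshold,
                            "peak": f.peak, "amplitude": f.amplitude,
                            "half_width": f.half_width, "fahp": f.fahp,
                            "max_dvdt": f.max_dvdt,
                            "threshold_time": f.threshold_time,
                            "peak_time": f.peak_time,
                        }
                    )
                row["threshold"] = float(np.mean([f.threshold for f in feats]))
                row["amplitude"] = float(np.mean([f.amplitude for f in feats]))
                row["half_width"] = float(np.mean([f.half_width for f in feats]))
                row["fahp"] = float(np.mean([f.fahp for f in feats]))
                row["max_dvdt"] = float(np.mean([f.max_dvdt for f in feats]))
        except ValueError as err:
            _qc(qc_log, cell_id, "ap_features_failed", f"{cond}: {err}")

    if "ramp" in by_label:
        thr = threshold_from_ramp(by_label["ramp"][0], config.detection, config.features)
        if thr is None:
            _qc(qc_log, cell_id, "ramp_no_spike", f"{cond}: ramp elicited no spikes")
        else:
            row["ramp_threshold"] = thr

    if curve is not None and "adaptation_ratio" in row:
        cls = classify_cell(curve, row["adaptation_ratio"], config=config.classification)
        row["classification"] = cls.label
        if cls.label == "unclassified":
            _qc(qc_log, cell_id, "unclassified", f"{cond}: {cls.evidence}")
    return row


#: per-cell scalar measures that feed paired comparisons, with their test
PAIRED_MEASURES = (
    ("rmp", "paired_t"),
    ("rin_cc", "paired_t"),
    ("rin_vc", "paired_t"),
    ("tau", "paired_t"),
    ("rheobase", "paired_t"),
    ("threshold", "paired_t"),
    ("amplitude", "paired_t"),
    ("half_width", "paired_t"),
    ("fahp", "paired_t"),
    ("max_dvdt", "paired_t"),
    ("ramp_threshold", "paired_t"),
    ("xhalf", "wilcoxon"),
    ("rising_rate", "wilcoxon"),
)


def _comparison_row(comp: PairedComparison) -> dict:
    df = comp.df
    if isinstance(df, tuple):
        df = f"{df[0]},{df[1]}"
    return {
        "measure": comp.measure_name, "test": comp.test,
        "statistic_name": comp.statistic_name, "statistic": comp.statistic,
        "df": df, "p_value": comp.p_value, "n": comp.n,
        "baseline_mean": comp.baseline_mean, "drug_mean": comp.drug_mean,
        "mean_difference": comp.mean_difference,
        "flags": "; ".join(comp.flags),
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every applicable analysis per cell per condition, then group stats."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    cells, manifest = load_cohort(config.input_dir)
    qc_log: list[dict] = []
    ap_rows: list[dict] = []
    summary_rows: list[dict] = []
    epsc_rows: list[dict] = []
    epsc_results: dict[str, object] = {}

    for cell_id, cell in sorted(cells.items()):
        try:
            for cond in CONDITIONS:
                if cond not in cell.sweeps:
                    continue
                summary_rows.append(
                    _analyze_condition(
                        cell_id, cond, cell.sweeps[cond], config, qc_log, ap_rows
                    )
                )
            if cell.epsc is not None:
                series = qc_series_resistance(cell.epsc, config.rs_cap_mohm)
                if series.truncated_at_s is not None:
                    _qc(
                        qc_log, cell_id, "rs_truncation",
                        f"series resistance exceeded {config.rs_cap_mohm} MOhm at "
                        f"{series.truncated_at_s:.0f} s; later events dropped",
                    )
                result = potentiation(series, amplitude_config=config.epsc_amplitude)
                if result.qc_excluded:
                    _qc(qc_log, cell_id, "epsc_excluded", result.qc_reason)
                else:
                    if result.window_deviation:
                        _qc(qc_log, cell_id, "epsc_window_deviation", result.window_deviation)
                    epsc_results[cell_id] = result
                for ev in series.events:
                    amp = (
                        ev.planted_amplitude_pa
                        if ev.sweep is None
                        else None
                    )
                    epsc_rows.append(
                        {
                            "cell": cell_id, "timestamp_s": ev.timestamp_s,
                            "series_resistance_mohm": ev.series_resistance_mohm,
                            "amplitude_pa": amp,
                        }
                    )
        except Exception as err:  # noqa: BLE001 - cohort must survive one bad cell
            _qc(qc_log, cell_id, "cell_failed", f"{type(err).__name__}: {err}")

    summary = pd.DataFrame(summary_rows)
    comparisons: list[dict] = []
    if not summary.empty and set(CONDITIONS) <= set(summary.get("condition", [])):
        wide = summary.set_index(["cell", "condition"])
        for measure, test in PAIRED_MEASURES:
            if measure not in summary.columns:
                continue
            pairs, cells_used = [], []
            for cell_id in sorted(summary["cell"].unique()):
                try:
                    b = wide.loc[(cell_id, "baseline"), measure]
                    d = wide.loc[(cell_id, "drug"), measure]
                except KeyError:
                    continue
                if pd.notna(b) and pd.notna(d):
                    pairs.append((float(b), float(d)))
                    cells_used.append(cell_id)
            if len(pairs) < 2:
                continue
            try:
                if test == "wilcoxon" and len(pairs) >= 5:
                    comp = wilcoxon_signed_rank(pairs, measure)
                else:
                    comp = paired_t(pairs, measure)
                comparisons.append(_comparison_row(comp))
            except ValueError as err:
                _qc(qc_log, "cohort", "comparison_failed", f"{measure}: {err}")

    if epsc_results:
        pairs = [
            (r.baseline_mean_pa, r.drug_mean_pa)
            for _, r in sorted(epsc_results.items())
        ]
        if len(pairs) >= 2:
            comp = paired_t(pairs, "epsc_amplitude")
            row = _comparison_row(comp)
            row["group_percent_change"] = float(
                np.mean([r.percent_change for r in epsc_results.values()])
            )
            comparisons.append(row)

    # firing output across the shared current grid: treatment main effect
    if not summary.empty and "max_rate" in summary.columns:
        fi_long = _fi_long_table(cells, config)
        if fi_long is not None:
            try:
                res = rm_anova_treatment(fi_long, "firing_rate")
                comparisons.append(_comparison_row(res.as_comparison("firing_rate")))
            except ValueError as err:
                _qc(qc_log, "cohort", "rm_anova_failed", str(err))

    provenance = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "package_version": __version__,
        "n_cells": len(cells),
        "input_dir": str(config.input_dir),
    }
    return RunReport(
        cell_summary=summary,
        ap_features=pd.DataFrame(ap_rows),
        comparisons=pd.DataFrame(comparisons),
        epsc_timecourse=pd.DataFrame(epsc_rows),
        qc_log=qc_log,
        provenance=provenance,
    )


def _fi_long_table(cells: dict, config: RunConfig) -> pd.DataFrame | None:
    """Long (cell, condition, step, rate) table for the repeated-measures ANOVA."""
    rows = []
    for cell_id, cell in sorted(cells.items()):
        for cond in CONDITIONS:
            if cond not in cell.sweeps or "fi" not in cell.sweeps[cond]:
                return None
            curve = build_fi_curve(cell.sweeps[cond]["fi"], config.detection)
            for cur, rate in zip(curve.currents, curve.rates):
                rows.append(
                    {"cell": cell_id, "condition": cond, "step": cur, "value": rate}
                )
    return pd.DataFrame(rows) if rows else None


def write_report(report: RunReport, out_dir) -> Path:
    """Archive all report tables, the QC log and provenance under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    for name, df in (
        ("cell_summary", report.cell_summary),
        ("ap_features", report.ap_features),
        ("comparisons", report.comparisons),
        ("epsc_timecourse", report.epsc_timecourse),
    ):
        df2 = df.copy()
        if not df2.empty:
            df2 = df2.sort_index(axis=1)
        df2.to_csv(out / f"{name}.csv", index=False, float_format=fmt)
    (out / "qc_log.json").write_text(
        json.dumps(report.qc_log, sort_keys=True, indent=2) + "\n"
    )
    (out / "provenance.json").write_text(
        json.dumps(report.provenance, sort_keys=True, indent=2) + "\n"
    )
    return out


def recovery_check(
    report: RunReport,
    manifest: GroundTruthManifest,
    tolerances: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Compare recovered group effects against the planted manifest values.

    For each planted group effect the recovered group mean difference is
    compared to the manifest mean of the per-cell realized values; ``tol``
    is an absolute tolerance per measure.  Returns a machine-readable
    pass/fail table.
    """
    tolerances = tolerances or {}
    summary = report.cell_summary
    if summary.empty:
        raise ValueError("report contains no cell summaries to check")
    report_cells = set(summary["cell"].unique())
    manifest_cells = {c.cell_id for c in manifest.cells}
    if not report_cells <= manifest_cells:
        raise ValueError(
            f"report cells {sorted(report_cells - manifest_cells)} missing from manifest"
        )

    wide = summary.set_index(["cell", "condition"])

    def recovered_delta(measure: str) -> float | None:
        if measure not in summary.columns:
            return None
        diffs = []
        for cell_id in sorted(report_cells):
            try:
                b = wide.loc[(cell_id, "baseline"), measure]
                d = wide.loc[(cell_id, "drug"), measure]
            except KeyError:
                continue
            if pd.notna(b) and pd.notna(d):
                diffs.append(float(d) - float(b))
        return float(np.mean(diffs)) if diffs else None

    checks = [
        ("delta_rmp", recovered_delta("rmp"), manifest.mean_realized_delta_rmp, 0.5),
        (
            "delta_rheobase", recovered_delta("rheobase"),
            manifest.mean_realized_delta_rheobase, 10.0,
        ),
        (
            "delta_threshold", recovered_delta("threshold"),
            manifest.mean_realized_delta_threshold, 1.0,
        ),
    ]
    rows = []
    for name, got, planted, default_tol in checks:
        if got is None:
            continue
        tol = tolerances.get(name, default_tol)
        rows.append(
            {
                "measure": name, "recovered": got, "planted": planted,
                "abs_error": abs(got - planted), "tolerance": tol,
                "passed": bool(abs(got - planted) <= tol),
            }
        )
    comp = report.comparisons
    if not comp.empty and "group_percent_change" in comp.columns:
        sub = comp[comp["measure"] == "epsc_amplitude"]
        if not sub.empty and pd.notna(sub.iloc[0].get("group_percent_change")):
            got = float(sub.iloc[0]["group_percent_change"])
            planted = manifest.mean_realized_percent_change
            tol = tolerances.get("epsc_percent_change", 10.0)
            rows.append(
                {
                    "measure": "epsc_percent_change", "recovered": got,
                    "planted": planted, "abs_error": abs(got - planted),
                    "tolerance": tol, "passed": bool(abs(got - planted) <= tol),
                }
            )
    if not rows:
        raise ValueError("no recoverable measures shared by report and manifest")
    return pd.DataFrame(rows)
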