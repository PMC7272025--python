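"""On-disk dataset layout: CSV sweeps with JSON sidecars, cohort manifest.

Layout::

    cohort/
      manifest.json                 # ground-truth manifest (synthetic cohorts)
      cell00/
        baseline/
          fi_0003.csv / .json       # two-column CSV (time_ms,value) + sidecar
          ...
        drug/
          ...
        epsc/
          series.json               # timestamps, Rs, drug onset, stim time
          event_0000.csv
          ...

All floats are written with a fixed format and JSON keys are sorted, so a
regeneration from the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .epsc_analysis import EPSCEvent, EPSCSeries
from .synthetic_data import (
    CellData,
    CellTruth,
    GroundTruthManifest,
    NeuronModelParams,
    PlantedEffects,
)
from .trace_features import Stimulus, Sweep

__all__ = [
    "write_sweep",
    "read_sweep",
    "write_cohort",
    "load_cohort",
    "write_manifest",
    "read_manifest",
]

_FLOAT_FMT = "%.6f"


def write_sweep(path: Path, sweep: Sweep, label: str, extra: dict | None = None) -> None:
    """Write one sweep as CSV plus a JSON sidecar with units and protocol fields."""
    arr = np.column_stack([sweep.time_ms, sweep.values])
    np.savetxt(path, arr, fmt=_FLOAT_FMT, delimiter=",", header="time_ms,value", comments="")
    meta = {
        "units": sweep.units,
        "sampling_rate_khz": sweep.sampling_khz,
        "label": label,
        "stimulus": dataclasses.asdict(sweep.stimulus),
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")


def read_sweep(path: Path) -> tuple[Sweep, dict]:
    meta = json.loads(path.with_suffix(".json").read_text())
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError(f"malformed sweep file {path}")
    stim = Stimulus(**meta["stimulus"])
    sweep = Sweep(
        time_ms=arr[:, 0],
        values=arr[:, 1],
        units=meta["units"],
        sampling_khz=meta["sampling_rate_khz"],
        stimulus=stim,
    )
    return sweep, meta


def _effects_to_dict(fx: PlantedEffects) -> dict:
    return dataclasses.asdict(fx)


def _params_to_dict(p: NeuronModelParams) -> dict:
    return dataclasses.asdict(p)


def write_manifest(path: Path, manifest: GroundTruthManifest) -> None:
    doc = {
        "seed": manifest.seed,
        "phenotype": manifest.phenotype,
        "effects": _effects_to_dict(manifest.effects),
        "noise_sd_mv": manifest.noise_sd_mv,
        "epsc_noise_cv": manifest.epsc_noise_cv,
        "cells": [
            {
                "cell_id": c.cell_id,
                "baseline_params": _params_to_dict(c.baseline),
                "drug_params": _params_to_dict(c.drug),
                "realized_delta_rmp": c.realized_delta_rmp,
                "realized_delta_threshold": c.realized_delta_threshold,
                "realized_delta_rheobase": c.realized_delta_rheobase,
                "realized_epsc_factor": c.realized_epsc_factor,
                "epsc_base_amplitude": c.epsc_base_amplitude,
                "rheobase_theory_baseline": c.rheobase_theory_baseline,
                "rheobase_theory_drug": c.rheobase_theory_drug,
            }
            for c in manifest.cells
        ],
    }
    path.write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")


def read_manifest(path: Path) -> GroundTruthManifest:
    doc = json.loads(path.read_text())
    cells = [
        CellTruth(
            cell_id=c["cell_id"],
            baseline=NeuronModelParams(**c["baseline_params"]),
            drug=NeuronModelParams(**c["drug_params"]),
            realized_delta_rmp=c["realized_delta_rmp"],
            realized_delta_threshold=c["realized_delta_threshold"],
            realized_delta_rheobase=c["realized_delta_rheobase"],
            realized_epsc_factor=c["realized_epsc_factor"],
            epsc_base_amplitude=c["epsc_base_amplitude"],
            rheobase_theory_baseline=c["rheobase_theory_baseline"],
            rheobase_theory_drug=c["rheobase_theory_drug"],
        )
        for c in doc["cells"]
    ]
    return GroundTruthManifest(
        seed=doc["seed"],
        phenotype=doc["phenotype"],
        effects=PlantedEffects(**doc["effects"]),
        noise_sd_mv=doc["noise_sd_mv"],
        epsc_noise_cv=doc["epsc_noise_cv"],
        cells=cells,
    )


def write_cohort(
    out_dir, cells: list[CellData], manifest: GroundTruthManifest, overwrite: bool = False
) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(out / "manifest.json", manifest)
    for cell in cells:
        cdir = out / cell.cell_id
        for cond, by_label in cell.sweeps.items():
            d = cdir / cond
            d.mkdir(parents=True, exist_ok=True)
            for label, sweeps in sorted(by_label.items()):
                for k, sw in enumerate(sweeps):
                    write_sweep(d / f"{label}_{k:04d}.csv", sw, label)
        if cell.epsc is not None:
            edir = cdir / "epsc"
            edir.mkdir(parents=True, exist_ok=True)
            series = cell.epsc
            doc = {
                "drug_onset_s": series.drug_onset_s,
                "holding_potential_mv": series.holding_potential_mv,
                "stim_time_ms": series.stim_time_ms,
                "events": [
                    {
                        "timestamp_s": ev.timestamp_s,
                        "series_resistance_mohm": ev.series_resistance_mohm,
                        "file": f"event_{k:04d}.csv" if ev.sweep is not None else None,
                    }
                    for k, ev in enumerate(series.events)
                ],
            }
            (edir / "series.json").write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")
            for k, ev in enumerate(series.events):
                if ev.sweep is not None:
                    arr = np.column_stack([ev.sweep.time_ms, ev.sweep.values])
                    np.savetxt(
                        edir / f"event_{k:04d}.csv", arr, fmt=_FLOAT_FMT,
                        delimiter=",", header="time_ms,value", comments="",
                    )
                    if k == 0:
                        meta = {
                            "units": "pA",
                            "sampling_rate_khz": ev.sweep.sampling_khz,
                            "stimulus": dataclasses.asdict(ev.sweep.stimulus),
                        }
                        (edir / "events_meta.json").write_text(
                            json.dumps(meta, sort_keys=True, indent=2) + "\n"
                        )
    return out


def load_cohort(path) -> tuple[dict[str, CellData], GroundTruthManifest | None]:
    """Read a cohort directory back into memory.

    Returns (cells keyed by id, manifest or None for non-synthetic data).
    Raises on an empty or malformed directory.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory {root} does not exist")
    cell_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not cell_dirs:
        raise ValueError(f"dataset directory {root} contains no cell directories")
    manifest = None
    mpath = root / "manifest.json"
    if mpath.exists():
        manifest = read_manifest(mpath)

    cells: dict[str, CellData] = {}
    for cdir in cell_dirs:
        sweeps: dict[str, dict[str, list[Sweep]]] = {}
        for cond_dir in sorted(d for d in cdir.iterdir() if d.is_dir() and d.name != "epsc"):
            by_label: dict[str, list[Sweep]] = {}
            for f in sorted(cond_dir.glob("*.csv")):
                sw, meta = read_sweep(f)
                by_label.setdefault(meta["label"], []).append(sw)
            sweeps[cond_dir.name] = by_label
        epsc = None
        edir = cdir / "epsc"
        if edir.is_dir():
            doc = json.loads((edir / "series.json").read_text())
            meta_path = edir / "events_meta.json"
            ev_meta = json.loads(meta_path.read_text()) if meta_path.exists() else None
            events = []
            for ev in doc["events"]:
                sweep = None
                if ev["file"] is not None:
                    arr = np.loadtxt(edir / ev["file"], delimiter=",", skiprows=1)
                    sweep = Sweep(
                        time_ms=arr[:, 0],
                        values=arr[:, 1],
                        units="pA",
                        sampling_khz=ev_meta["sampling_rate_khz"],
                        stimulus=Stimulus(**ev_meta["stimulus"]),
                    )
                events.append(
                    EPSCEvent(
                        timestamp_s=ev["timestamp_s"],
                        sweep=sweep,
                        series_resistance_mohm=ev["series_resistance_mohm"],
                    )
                )
            epsc = EPSCSeries(
                events=events,
                drug_onset_s=doc["drug_onset_s"],
                holding_potential_mv=doc["holding_potential_mv"],
                stim_time_ms=doc["stim_time_ms"],
            )
        cells[cdir.name] = CellData(cell_id=cdir.name, sweeps=sweeps, epsc=epsc)
    return cells, manifest
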