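"""On-disk trial container and analysis configuration.

A container is a directory holding ``manifest.json`` (schema version, cell
records, trial records) and one CSV per trial with columns ``time_s,value``
(mV for current-clamp V_m trials, pA for voltage-clamp EPSC trials).
Values are written with 12 significant digits, so a write/read round-trip
is exact to ~1e-12 relative.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .epsc import EpscTrial
from .traces import VmTrial

SCHEMA_VERSION = 1


class ContainerFormatError(Exception):
    """Malformed or inconsistent on-disk container."""


@dataclass
class CellRecord:
    cell_id: str
    condition: str = ""
    access_resistance_MOhm: float | None = None
    depth_um: float | None = None
    sampling_rate_Hz: float | None = None


def _trial_record(trial: VmTrial | EpscTrial) -> dict:
    if isinstance(trial, VmTrial):
        return {
            "cell_id": trial.cell_id,
            "trial_id": trial.trial_id,
            "kind": "vm",
            "direction_deg": trial.direction,
            "stim_onset_s": trial.stim_onset,
            "stim_dur_s": trial.stim_dur,
            "sampling_rate_Hz": trial.sampling_rate,
            "n_samples": int(trial.samples.size),
        }
    return {
        "cell_id": trial.cell_id,
        "trial_id": trial.trial_id,
        "kind": "epsc",
        "ttl_time_s": trial.ttl_time,
        "sampling_rate_Hz": trial.sampling_rate,
        "n_samples": int(trial.current.size),
    }


def write_container(
    path: str | Path,
    cells: Iterable[CellRecord],
    trials: Iterable[VmTrial | EpscTrial],
) -> None:
    """Write cells and trials to a directory container."""
    path = Path(path)
    (path / "arrays").mkdir(parents=True, exist_ok=True)
    cells = list(cells)
    trials = list(trials)
    cell_ids = {c.cell_id for c in cells}
    records = []
    for t in trials:
        if t.cell_id not in cell_ids:
            raise ContainerFormatError(f"trial {t.trial_id!r} references unknown cell {t.cell_id!r}")
        rec = _trial_record(t)
        rec["path"] = f"arrays/{t.cell_id}__{t.trial_id}.csv"
        records.append(rec)
        data = t.samples if isinstance(t, VmTrial) else t.current
        time_s = np.arange(data.size) / t.sampling_rate
        np.savetxt(
            path / rec["path"],
            np.column_stack([time_s, data]),
            delimiter=",",
            header="time_s,value",
            comments="",
            fmt="%.12g",
        )
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "cells": [dataclasses.asdict(c) for c in cells],
        "trials": records,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_container(path: str | Path) -> tuple[list[CellRecord], list[VmTrial | EpscTrial]]:
    """Read a directory container back into cell records and trial objects."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ContainerFormatError(f"missing manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ContainerFormatError(
            f"unsupported schema version {manifest.get('schema_version')!r}"
        )
    cells = [CellRecord(**c) for c in manifest["cells"]]
    cell_map = {c.cell_id: c for c in cells}
    trials: list[VmTrial | EpscTrial] = []
    for rec in manifest["trials"]:
        if rec["cell_id"] not in cell_map:
            raise ContainerFormatError(
                f"trial {rec['trial_id']!r} references unknown cell {rec['cell_id']!r}"
            )
        arr = np.loadtxt(path / rec["path"], delimiter=",", skiprows=1)
        values = arr[:, 1]
        fs = rec["sampling_rate_Hz"]
        if abs(values.size - rec["n_samples"]) > 1:
            raise ContainerFormatError(
                f"trial {rec['trial_id']!r}: {values.size} samples, manifest says {rec['n_samples']}"
            )
        cell = cell_map[rec["cell_id"]]
        if rec["kind"] == "vm":
            trials.append(
                VmTrial(
                    samples=values,
                    sampling_rate=fs,
                    stim_onset=rec["stim_onset_s"],
                    stim_dur=rec["stim_dur_s"],
                    direction=rec.get("direction_deg"),
                    cell_id=rec["cell_id"],
                    trial_id=rec["trial_id"],
                    condition=cell.condition,
                )
            )
        elif rec["kind"] == "epsc":
            trials.append(
                EpscTrial(
                    current=values,
                    sampling_rate=fs,
                    ttl_time=rec["ttl_time_s"],
                    cell_id=rec["cell_id"],
                    trial_id=rec["trial_id"],
                    access_resistance=cell.access_resistance_MOhm,
                    depth=cell.depth_um,
                    group=cell.condition,
                )
            )
        else:
            raise ContainerFormatError(f"unknown trial kind {rec['kind']!r}")
    return cells, trials


_CONFIG_FIELDS = {
    # windows, seconds relative to stimulus onset
    "response_window": (0.05, 0.25),
    "baseline_window": (2.5, 4.7),
    "tuning_response_window": (0.05, 0.55),
    "tuning_baseline_window": (2.5, 3.5),
    "osc_response_window": (0.0, 0.5),
    "osc_baseline_window": (4.5, 5.0),
    # detector / filters
    "osc_ratio_threshold": 10.0,
    "osc_baseline_mode": "average",
    "filter_order": 4,
    "spike_threshold_mV": 15.0,
    # resampling
    "n_reps": 2000,
    "seed": 0,
}


@dataclass
class AnalysisConfig:
    """Every tunable of the analysis arcs, with the defaults of the study.

    Unknown keys in a config file are rejected rather than ignored.
    """

    response_window: tuple = _CONFIG_FIELDS["response_window"]
    baseline_window: tuple = _CONFIG_FIELDS["baseline_window"]
    tuning_response_window: tuple = _CONFIG_FIELDS["tuning_response_window"]
    tuning_baseline_window: tuple = _CONFIG_FIELDS["tuning_baseline_window"]
    osc_response_window: tuple = _CONFIG_FIELDS["osc_response_window"]
    osc_baseline_window: tuple = _CONFIG_FIELDS["osc_baseline_window"]
    osc_ratio_threshold: float = 10.0
    osc_baseline_mode: str = "average"
    filter_order: int = 4
    spike_threshold_mV: float = 15.0
    n_reps: int = 2000
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("response_window", "baseline_window", "tuning_response_window",
                    "tuning_baseline_window", "osc_response_window", "osc_baseline_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
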