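"""Reporting layer: the two analysis arcs as per-cell and group tables.

``run_familiarity_pipeline`` reproduces the single-direction arc
(oscillation probability, band magnitudes, V_m peak windows I-III,
baseline-subtracted firing rate, naive vs experienced); ``run_tuning_pipeline``
the 12-direction arc (per-direction rates, split-half OSI/DSI, band
magnitude and ITPC by direction class, spike phases). Group comparisons are
two-sided Mann-Whitney U tests with Benjamini-Hochberg correction within
each table — reporting glue around the per-cell numbers, every one of which
comes from a single module operation.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from . import spectral, traces, tuning
from .containers import AnalysisConfig
from .traces import VmTrial, WindowSpec
from .tuning import TuningDataset


def group_trials_by_cell(trials: Sequence[VmTrial]) -> dict[str, list[VmTrial]]:
    by_cell: dict[str, list[VmTrial]] = defaultdict(list)
    for t in trials:
        by_cell[t.cell_id].append(t)
    return dict(by_cell)


def familiarity_cell_row(
    vm_trials: Sequence[VmTrial], config: AnalysisConfig = AnalysisConfig()
) -> dict:
    """All single-direction metrics for one cell."""
    spike_trains = [traces.detect_spikes(t, thresh_mV=config.spike_threshold_mV) for t in vm_trials]
    clean = [traces.remove_spikes(t) for t in vm_trials]
    criterion = spectral.OscillationCriterion(
        response=tuple(config.osc_response_window),
        baseline=tuple(config.osc_baseline_window),
        ratio_threshold=config.osc_ratio_threshold,
    )
    _, osc_prob = spectral.detect_oscillation_trials(
        clean, criterion, baseline_mode=config.osc_baseline_mode
    )
    resp_win = tuple(config.response_window)
    mags = {
        f"mag_{band.lo:g}_{band.hi:g}_mV": float(
            np.mean([spectral.band_magnitude(t, band, resp_win) for t in clean])
        )
        for band in spectral.DEFAULT_BANDS
    }
    peaks = np.mean(
        [traces.delta_vm_peaks(t, baseline=tuple(config.baseline_window)) for t in clean],
        axis=0,
    )
    windows = WindowSpec(response=resp_win, baseline=tuple(config.baseline_window))
    rate = traces.baseline_subtracted_rate(
        spike_trains, windows, stim_onset=vm_trials[0].stim_onset
    )
    row = {
        "cell_id": vm_trials[0].cell_id,
        "condition": vm_trials[0].condition,
        "n_trials": len(vm_trials),
        "osc_probability": osc_prob,
        **mags,
        "dvm_I_mV": peaks[0],
        "dvm_II_mV": peaks[1],
        "dvm_III_mV": peaks[2],
        "rate_baseline_subtracted_Hz": rate,
    }
    return row


def group_summary(per_cell: pd.DataFrame, group_col: str = "condition") -> pd.DataFrame:
    """Two-sided Mann-Whitney U per metric column, BH-corrected within table."""
    groups = sorted(per_cell[group_col].unique())
    metrics = [
        c for c in per_cell.columns
        if c not in (group_col, "cell_id", "n_trials") and pd.api.types.is_numeric_dtype(per_cell[c])
    ]
    rows = []
    for m in metrics:
        row = {"metric": m}
        for g in groups:
            row[f"mean_{g}"] = per_cell.loc[per_cell[group_col] == g, m].mean()
        if len(groups) == 2:
            a = per_cell.loc[per_cell[group_col] == groups[0], m]
            b = per_cell.loc[per_cell[group_col] == groups[1], m]
            if a.nunique() > 1 or b.nunique() > 1 or a.iloc[0] != b.iloc[0]:
                u, p = mannwhitneyu(a, b, alternative="two-sided")
            else:
                u, p = np.nan, 1.0
            row["U"] = u
            row["p"] = p
        rows.append(row)
    out = pd.DataFrame(rows)
    if "p" in out.columns and len(out):
        out["p_bh"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    return out


def run_familiarity_pipeline(
    cells: dict[str, list[VmTrial]], config: AnalysisConfig = AnalysisConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell metrics table + group summary for single-direction data.

    ``cells`` maps cell_id to that cell's V_m trials. An empty input yields
    two empty tables. Deterministic for a given input and config.
    """
    rows = [familiarity_cell_row(trs, config) for trs in cells.values() if trs]
    per_cell = pd.DataFrame(rows)
    if per_cell.empty:
        return per_cell, pd.DataFrame()
    per_cell = per_cell.sort_values("cell_id", ignore_index=True)
    return per_cell, group_summary(per_cell)


def tuning_cell_row(ds: TuningDataset, config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Selectivity, class rates, band magnitude/ITPC per class, for one cell."""
    sel = tuning.split_half_selectivity(ds, n_reps=config.n_reps, seed=config.seed)
    r_pref, r_opp, r_orth = tuning.response_rates_by_class(ds)
    pref = tuning.preferred_direction(ds)
    classes = tuning.direction_classes(pref)
    resp_win = tuple(config.tuning_response_window)
    row = {
        "cell_id": ds.cell_id,
        "condition": ds.condition,
        "pref_direction_deg": pref,
        "osi": sel.osi,
        "dsi": sel.dsi,
        "rate_pref_Hz": r_pref,
        "rate_opp_Hz": r_opp,
        "rate_orth_Hz": r_orth,
    }
    for label, dirs in classes.items():
        vms = [traces.remove_spikes(vm) for d in dirs for vm, _ in ds.trials[d]]
        row[f"mag_theta_{label}_mV"] = float(
            np.mean([spectral.band_magnitude(t, spectral.THETA_BAND, resp_win) for t in vms])
        )
        W, freqs = spectral.wavelet_transform(vms)
        band = (freqs >= 4) & (freqs <= 7)
        t0 = vms[0].stim_onset + resp_win[0]
        t1 = vms[0].stim_onset + resp_win[1]
        tmask = (vms[0].times >= t0) & (vms[0].times < t1)
        row[f"itpc_theta_{label}"] = float(spectral.itpc(W)[band][:, tmask].mean())
    return row


def tuning_phase_table(
    ds: TuningDataset, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Per-spike 4-7 Hz phase samples labelled by direction class."""
    pref = tuning.preferred_direction(ds)
    classes = tuning.direction_classes(pref)
    rows = []
    for label, dirs in classes.items():
        for d in dirs:
            for vm, spk in ds.trials[d]:
                ps = tuning.spike_phases(
                    vm, spk, window=tuple(config.tuning_response_window), direction_class=label
                )
                rows.extend(
                    {
                        "cell_id": ds.cell_id,
                        "trial_id": vm.trial_id,
                        "direction_deg": d,
                        "direction_class": label,
                        "phase_rad": ph,
                    }
                    for ph in ps.phases
                )
    return pd.DataFrame(rows, columns=["cell_id", "trial_id", "direction_deg", "direction_class", "phase_rad"])


def run_tuning_pipeline(
    datasets: Sequence[TuningDataset], config: AnalysisConfig = AnalysisConfig()
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-cell tuning table, group summary, and pooled phase samples."""
    rows = [tuning_cell_row(ds, config) for ds in datasets]
    per_cell = pd.DataFrame(rows)
    phases = (
        pd.concat([tuning_phase_table(ds, config) for ds in datasets], ignore_index=True)
        if datasets
        else pd.DataFrame()
    )
    if per_cell.empty:
        return per_cell, pd.DataFrame(), phases
    per_cell = per_cell.sort_values("cell_id", ignore_index=True)
    return per_cell, group_summary(per_cell), phases
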