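"""Optogenetically evoked EPSC feature extraction and cell-level QC.

EPSCs are inward (negative) currents recorded in voltage clamp after a light
pulse (TTL). Features per trial or per averaged trace: amplitude (positive
magnitude of the baseline-subtracted inward peak within 0-40 ms after the
TTL), latency (first crossing of 5% of the amplitude after the TTL, in ms)
and peak time. Cells are kept when their mean latency is below 3.5 ms
(monosynaptic) and their access resistance is at most 60 MOhm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np


@dataclass
class EpscTrial:
    """One voltage-clamp sweep (pA) with the light-pulse TTL time (s)."""

    current: np.ndarray
    sampling_rate: float
    ttl_time: float
    cell_id: str = ""
    trial_id: str = ""
    access_resistance: float | None = None  # MOhm
    depth: float | None = None  # um
    group: str = ""

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.ttl_time < self.current.size / self.sampling_rate:
            raise ValueError("ttl_time outside trace")


@dataclass
class EpscFeatures:
    amplitude: float  # pA, >= 0 (magnitude of the inward peak)
    latency: float | None  # ms after TTL; None when below detection
    peak_time: float | None  # ms after TTL

    @property
    def detected(self) -> bool:
        return self.latency is not None


def extract_epsc(
    trial: EpscTrial,
    baseline_dur: float = 0.2,
    peak_window_ms: float = 40.0,
    noise_mult: float = 3.0,
) -> EpscFeatures:
    """Extract amplitude/latency/peak time of the light-evoked EPSC.

    The baseline is the mean current over ``baseline_dur`` seconds before
    the TTL; the inward peak is searched in (0, ``peak_window_ms``] after
    the TTL. A deflection smaller than ``noise_mult`` baseline SDs counts
    as below detection (amplitude 0, latency undefined). The latency is the
    first post-TTL sample at which the baseline-subtracted current crosses
    5% of the amplitude in the inward direction.
    """
    fs = trial.sampling_rate
    i_ttl = int(round(trial.ttl_time * fs))
    n_base = int(round(baseline_dur * fs))
    if i_ttl - n_base < 0:
        raise ValueError(f"need {baseline_dur} s of pre-TTL baseline")
    base_seg = trial.current[i_ttl - n_base : i_ttl]
    baseline = float(base_seg.mean())
    noise_sd = float(base_seg.std())

    i_end = min(i_ttl + int(round(peak_window_ms * 1e-3 * fs)), trial.current.size - 1)
    seg = trial.current[i_ttl + 1 : i_end + 1] - baseline
    if seg.size == 0:
        raise ValueError("no samples in the peak window")
    i_peak = int(np.argmin(seg))  # inward = most negative
    amplitude = -float(seg[i_peak])
    if amplitude <= noise_mult * noise_sd:
        return EpscFeatures(amplitude=0.0, latency=None, peak_time=None)

    peak_time_ms = (i_peak + 1) / fs * 1e3
    crossing = np.flatnonzero(seg[: i_peak + 1] <= -0.05 * amplitude)
    latency_ms = (crossing[0] + 1) / fs * 1e3
    return EpscFeatures(amplitude=amplitude, latency=latency_ms, peak_time=peak_time_ms)


def average_cell_epsc(trials: Sequence[EpscTrial], **kwargs) -> EpscFeatures:
    """Features of the trial-averaged trace (typically 10 trials per cell)."""
    if not trials:
        raise ValueError("no trials")
    first = trials[0]
    if any(
        t.current.size != first.current.size
        or t.sampling_rate != first.sampling_rate
        or t.ttl_time != first.ttl_time
        for t in trials
    ):
        raise ValueError("trials must share length, rate and TTL time for averaging")
    mean = np.mean([t.current for t in trials], axis=0)
    return extract_epsc(replace(first, current=mean), **kwargs)


@dataclass
class CellQC:
    cell_id: str
    kept: bool
    reasons: tuple[str, ...]


def qc_filter_cells(
    cells: Sequence[tuple[str, float | None, float | None]],
    max_latency_ms: float = 3.5,
    max_access_mohm: float = 60.0,
) -> tuple[list[str], list[CellQC]]:
    """Keep cells with mean EPSC latency < 3.5 ms and Ra <= 60 MOhm.

    ``cells`` is a sequence of (cell_id, mean_latency_ms, access_resistance);
    a missing (None) latency means no detectable monosynaptic response.
    Returns (kept cell_ids, full per-cell log).
    """
    kept, log = [], []
    for cell_id, latency, ra in cells:
        reasons = []
        if latency is None or not latency < max_latency_ms:
            reasons.append(f"latency {latency} ms not < {max_latency_ms} ms")
        if ra is not None and ra > max_access_mohm:
            reasons.append(f"access resistance {ra} MOhm > {max_access_mohm} MOhm")
        ok = not reasons
        if ok:
            kept.append(cell_id)
        log.append(CellQC(cell_id, ok, tuple(reasons)))
    return kept, log


def membrane_resistance(
    step_currents_pA: Sequence[float], steady_voltages_mV: Sequence[float]
) -> float:
    """Membrane resistance (MOhm) as the least-squares slope of V vs I.

    mV per pA equals GOhm, hence the factor 1000 to MOhm.
    """
    i = np.asarray(step_currents_pA, float)
    v = np.asarray(steady_voltages_mV, float)
    if i.size != v.size or i.size < 2:
        raise ValueError("need >= 2 matching (I, V) points")
    slope = np.polyfit(i, v, 1)[0]  # mV/pA = GOhm
    return float(slope * 1e3)
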