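"""Trial data model and membrane-potential trace operations.

The unit of subthreshold analysis is a :class:`VmTrial` (one current-clamp
sweep in mV with its stimulus metadata); the unit of suprathreshold analysis
is a :class:`SpikeTrain` (action-potential times in seconds from trial start).
This module provides action-potential removal (running median), AP detection
(dual Hanning-window high-pass + threshold), PSTH/rate computation with
Gaussian smoothing, and baseline-referenced V_m peak statistics.

Conventions: all times in seconds, voltages in mV, windows half-open
``[start, end)`` and expressed relative to the stimulus onset unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage


@dataclass
class VmTrial:
    """One membrane-potential trace with its stimulus metadata.

    Parameters
    ----------
    samples : array of mV, shape (n,)
    sampling_rate : Hz
    stim_onset, stim_dur : s, stimulus timing relative to trial start
    direction : degrees of grating drift, or None for single-direction data
    """

    samples: np.ndarray
    sampling_rate: float
    stim_onset: float
    stim_dur: float
    direction: float | None = None
    cell_id: str = ""
    trial_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.stim_onset < 0 or self.stim_onset + self.stim_dur > self.duration + 1e-9:
            raise ValueError("stimulus window must lie within the trial")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def window_slice(self, start: float, end: float, relative: bool = True) -> slice:
        """Sample slice for the half-open window [start, end) in seconds.

        ``relative=True`` interprets the window relative to stimulus onset.
        """
        if relative:
            start += self.stim_onset
            end += self.stim_onset
        i0 = int(round(start * self.sampling_rate))
        i1 = int(round(end * self.sampling_rate))
        if i0 < 0 or i1 > self.samples.size or i0 >= i1:
            raise ValueError(f"window [{start}, {end}) s outside trial")
        return slice(i0, i1)


@dataclass
class SpikeTrain:
    """Action-potential times for one trial, seconds from trial start."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (
            np.any(np.diff(self.times) <= 0)
            or self.times[0] < 0
            or self.times[-1] > self.duration
        ):
            raise ValueError("spike times must be strictly increasing within [0, duration]")

    def count_in(self, start: float, end: float) -> int:
        return int(np.sum((self.times >= start) & (self.times < end)))

    def rate_in(self, start: float, end: float) -> float:
        return self.count_in(start, end) / (end - start)


@dataclass
class Psth:
    """Peristimulus time histogram: trial-averaged firing rate per bin (Hz)."""

    bin_edges: np.ndarray
    rate: np.ndarray
    smoothed_rate: np.ndarray
    normalized_rate: np.ndarray
    n_trials: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class WindowSpec:
    """Response and baseline windows, seconds relative to stimulus onset."""

    response: tuple[float, float]
    baseline: tuple[float, float]

    def __post_init__(self) -> None:
        (r0, r1), (b0, b1) = self.response, self.baseline
        if not (r0 < r1 and b0 < b1):
            raise ValueError("windows must have positive length")
        if max(r0, b0) < min(r1, b1):
            raise ValueError("response and baseline windows overlap")


#: Windows of the single-direction (familiarity) firing-rate analysis.
FAMILIARITY_WINDOWS = WindowSpec(response=(0.05, 0.25), baseline=(2.5, 4.7))
#: Windows of the 12-direction tuning firing-rate analysis.
TUNING_WINDOWS = WindowSpec(response=(0.05, 0.55), baseline=(2.5, 3.5))
#: V_m peak windows I/II/III, one per cycle of the 5-Hz oscillation.
DELTA_VM_WINDOWS = ((0.05, 0.25), (0.25, 0.45), (0.45, 0.65))


def _odd_window_samples(window_ms: float, sampling_rate: float) -> int:
    n = int(math.ceil(window_ms * 1e-3 * sampling_rate))
    if n % 2 == 0:
        n += 1
    return max(n, 3)


def remove_spikes(trial: VmTrial, window_ms: float = 12.5) -> VmTrial:
    """Remove action potentials with a running median filter.

    A 12.5-ms median window (rounded up to an odd sample count) strips the
    fast AP transients while leaving the subthreshold V_m essentially
    unchanged; edges are handled by replication.
    """
    n = _odd_window_samples(window_ms, trial.sampling_rate)
    if n > trial.samples.size:
        raise ValueError("median window longer than trace")
    filtered = ndimage.median_filter(trial.samples, size=n, mode="nearest")
    return replace(trial, samples=filtered)


def _hanning_smooth(x: np.ndarray, window_ms: float, sampling_rate: float) -> np.ndarray:
    n = max(int(round(window_ms * 1e-3 * sampling_rate)), 3)
    kernel = np.hanning(n)
    kernel /= kernel.sum()  # unit sum: keeps the local mean in mV
    return ndimage.convolve1d(x, kernel, mode="reflect")


def detect_spikes(
    trial: VmTrial,
    fine_ms: float = 0.5,
    coarse_ms: float = 500.0,
    thresh_mV: float = 15.0,
) -> SpikeTrain:
    """Detect action potentials on the raw trace.

    The trace is smoothed with a fine (0.5 ms) and a coarse (500 ms) Hanning
    window; the coarse version estimates the slow V_m fluctuation and is
    subtracted from the fine version. Peaks of the difference exceeding
    ``thresh_mV`` are APs: one event per contiguous supra-threshold run, at
    the run's maximum (earliest sample on ties).
    """
    x = trial.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    if x.size <= int(coarse_ms * 1e-3 * trial.sampling_rate):
        raise ValueError("trace shorter than the coarse smoothing window")
    d = _hanning_smooth(x, fine_ms, trial.sampling_rate) - _hanning_smooth(
        x, coarse_ms, trial.sampling_rate
    )
    above = d > thresh_mV
    if not above.any():
        return SpikeTrain(np.empty(0), trial.duration)
    # contiguous supra-threshold runs -> one spike each at the argmax
    padded = np.diff(np.r_[False, above, False].astype(np.int8))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    idx = np.array([s + int(np.argmax(d[s:e])) for s, e in zip(starts, stops)])
    return SpikeTrain(idx / trial.sampling_rate, trial.duration)


def compute_psth(
    trains: Sequence[SpikeTrain],
    bin_ms: float = 10.0,
    gauss_win_ms: float = 200.0,
    gauss_sigma_ms: float = 40.0,
) -> Psth:
    """Trial-averaged PSTH with 10-ms bins and Gaussian smoothing.

    ``rate[b] = total count in bin b / (n_trials * bin width)``. The smoothed
    rate convolves with a truncated, unit-sum Gaussian (200-ms support,
    40-ms sigma); the normalized rate divides the smoothed rate by its
    per-cell maximum (zeros if the cell never fired).
    """
    if not trains:
        raise ValueError("need at least one trial")
    duration = max(t.duration for t in trains)
    bin_w = bin_ms * 1e-3
    edges = np.arange(0.0, duration + bin_w / 2, bin_w)
    counts = np.zeros(edges.size - 1)
    for t in trains:
        counts += np.histogram(t.times, bins=edges)[0]
    rate = counts / (len(trains) * bin_w)

    half = int(round(gauss_win_ms / 2.0 / bin_ms))
    i = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (i * bin_ms / gauss_sigma_ms) ** 2)
    kernel /= kernel.sum()
    smoothed = ndimage.convolve1d(rate, kernel, mode="reflect")
    peak = smoothed.max()
    normalized = smoothed / peak if peak > 0 else np.zeros_like(smoothed)
    return Psth(edges, rate, smoothed, normalized, len(trains))


def baseline_subtracted_rate(
    trains: Sequence[SpikeTrain],
    windows: WindowSpec = FAMILIARITY_WINDOWS,
    stim_onset: float = 0.0,
) -> float:
    """Mean firing rate in the response window minus the baseline rate (Hz)."""
    r0, r1 = (w + stim_onset for w in windows.response)
    b0, b1 = (w + stim_onset for w in windows.baseline)
    resp = np.mean([t.rate_in(r0, r1) for t in trains])
    base = np.mean([t.rate_in(b0, b1) for t in trains])
    return float(resp - base)


def zscore_rate(psth: Psth, baseline: tuple[float, float]) -> np.ndarray:
    """Z-score the smoothed PSTH against a baseline window (absolute s)."""
    centers = psth.bin_centers
    mask = (centers >= baseline[0]) & (centers < baseline[1])
    if not mask.any():
        raise ValueError("baseline window contains no bins")
    mu = psth.smoothed_rate[mask].mean()
    sd = psth.smoothed_rate[mask].std()
    if sd == 0:
        raise ValueError("baseline SD is zero; z-score undefined")
    return (psth.smoothed_rate - mu) / sd


def delta_vm_peaks(
    trial: VmTrial,
    windows: Sequence[tuple[float, float]] = DELTA_VM_WINDOWS,
    baseline: tuple[float, float] = (2.5, 4.7),
) -> tuple[float, ...]:
    """Baseline-subtracted V_m peaks in successive post-onset windows.

    Windows default to I/II/III (0.05-0.25, 0.25-0.45, 0.45-0.65 s after
    onset), one per cycle of the 5-Hz oscillation; the mean V_m of the
    baseline window (2.5-4.7 s after onset) is subtracted from each peak.
    The input should be spike-removed.
    """
    base = float(np.mean(trial.samples[trial.window_slice(*baseline)]))
    return tuple(
        float(np.max(trial.samples[trial.window_slice(w0, w1)]) - base)
        for w0, w1 in windows
    )
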