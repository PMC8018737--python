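"""Spectral analysis of subthreshold membrane potential.

Power spectra (FFT periodogram), band magnitudes (zero-phase Butterworth
bandpass + Hilbert envelope), complex Morlet wavelet time-frequency maps,
intertrial phase coherence (ITPC), and the oscillation-trial detector
(response-window 4-7 Hz power > 10x the averaged baseline power).

All operations expect spike-removed traces; use :func:`v1osc.traces.remove_spikes`
first when the recording contains action potentials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal

from .traces import VmTrial


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError("need 0 < lo < hi")


THETA_BAND = BandSpec("4-7 Hz", 4.0, 7.0)
ALPHA_BAND = BandSpec("8-12 Hz", 8.0, 12.0)
BETA_BAND = BandSpec("13-30 Hz", 13.0, 30.0)
DEFAULT_BANDS = (THETA_BAND, ALPHA_BAND, BETA_BAND)


@dataclass
class Spectrogram:
    """Wavelet time-frequency result: power (and optionally ITPC) per (f, t)."""

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray  # (n_freqs, n_times), trial-averaged
    itpc: np.ndarray | None = None
    power_db: np.ndarray | None = None


@dataclass(frozen=True)
class OscillationCriterion:
    """Oscillation-trial rule: response band power > threshold x baseline.

    Defaults follow the single-direction analysis: 4-7 Hz band, response
    window = stimulus onset to 0.5 s after, baseline = 4.5-5.0 s after
    onset, threshold 10.
    """

    band: BandSpec = THETA_BAND
    response: tuple[float, float] = (0.0, 0.5)
    baseline: tuple[float, float] = (4.5, 5.0)
    ratio_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")


def default_wavelet_freqs(n: int = 40, lo: float = 2.0, hi: float = 80.0) -> np.ndarray:
    """40 log-spaced wavelet frequencies from 2 to 80 Hz."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def default_wavelet_cycles(freqs: np.ndarray, lo: float = 3.0, hi: float = 10.0) -> np.ndarray:
    """Cycle counts mapped linearly from 3 to 10 across the frequency grid."""
    freqs = np.asarray(freqs, float)
    if freqs.size == 1:
        return np.array([lo])
    return lo + (hi - lo) * np.linspace(0.0, 1.0, freqs.size)


def power_spectrum(
    trial: VmTrial, window: tuple[float, float] | None = None, relative: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT periodogram of a (spike-removed) V_m window.

    The window mean is removed before the transform. Returns (freqs in Hz,
    power spectral density in mV^2/Hz).
    """
    if window is None:
        x = trial.samples
    else:
        x = trial.samples[trial.window_slice(*window, relative=relative)]
    freqs, pxx = signal.periodogram(x, fs=trial.sampling_rate, detrend="constant")
    return freqs, pxx


def bandpass(
    x: np.ndarray, band: BandSpec, sampling_rate: float, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass."""
    sos = signal.butter(order, [band.lo, band.hi], btype="bandpass", fs=sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def band_magnitude(
    trial: VmTrial,
    band: BandSpec = THETA_BAND,
    window: tuple[float, float] | None = None,
    relative: bool = True,
) -> float:
    """Mean oscillation amplitude (mV) of a frequency band over a window.

    The whole trace is bandpassed (zero-phase Butterworth order 4), the
    analytic-signal envelope is taken, and its mean over the window is
    returned. For a pure in-band sinusoid of amplitude A this is A.
    """
    bp = bandpass(trial.samples, band, trial.sampling_rate)
    env = np.abs(signal.hilbert(bp))
    if window is not None:
        env = env[trial.window_slice(*window, relative=relative)]
    return float(env.mean())


def band_power(
    trial: VmTrial,
    band: BandSpec,
    window: tuple[float, float],
    relative: bool = True,
) -> float:
    """Mean squared amplitude (mV^2) of the bandpassed signal over a window."""
    bp = bandpass(trial.samples, band, trial.sampling_rate)
    seg = bp[trial.window_slice(*window, relative=relative)]
    return float(np.mean(seg**2))


def _morlet_kernel(freq: float, n_cycles: float, sampling_rate: float) -> np.ndarray:
    """Complex Morlet wavelet, Gaussian envelope normalized to unit sum."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    env /= env.sum()
    return env * np.exp(2j * np.pi * freq * t)


def wavelet_transform(
    trials: Sequence[VmTrial] | Sequence[np.ndarray],
    sampling_rate: float | None = None,
    freqs: np.ndarray | None = None,
    cycles: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Complex Morlet wavelet coefficients for a set of trials.

    Convolves each trace with complex Morlet wavelets on a 40-frequency
    log grid (2-80 Hz) whose cycle count grows linearly from 3 to 10 with
    grid position. Traces are reflect-padded by the longest wavelet
    half-length before convolution.

    Returns ``(W, freqs)`` with ``W`` complex of shape
    (n_trials, n_freqs, n_times).
    """
    arrays = [t.samples if isinstance(t, VmTrial) else np.asarray(t, float) for t in trials]
    if sampling_rate is None:
        if not isinstance(trials[0], VmTrial):
            raise ValueError("sampling_rate required for bare arrays")
        sampling_rate = trials[0].sampling_rate
    if freqs is None:
        freqs = default_wavelet_freqs()
    freqs = np.asarray(freqs, float)
    if cycles is None:
        cycles = default_wavelet_cycles(freqs)
    n_times = arrays[0].size
    if any(a.size != n_times for a in arrays):
        raise ValueError("all trials must have equal length")

    kernels = [_morlet_kernel(f, c, sampling_rate) for f, c in zip(freqs, cycles)]
    pad = max(k.size // 2 for k in kernels)
    W = np.empty((len(arrays), freqs.size, n_times), dtype=complex)
    for i, a in enumerate(arrays):
        padded = np.pad(a - a.mean(), pad, mode="reflect")
        for j, k in enumerate(kernels):
            conv = signal.fftconvolve(padded, k, mode="same")
            W[i, j] = conv[pad : pad + n_times]
    return W, freqs


def wavelet_power_db(
    W: np.ndarray,
    times: np.ndarray,
    baseline: tuple[float, float],
) -> np.ndarray:
    """Trial-averaged wavelet power in dB relative to a baseline window.

    ``power_db(f, t) = 10 log10(mean_trials |W|^2 / mean baseline power(f))``,
    the display normalization of time-frequency maps.
    """
    power = np.mean(np.abs(W) ** 2, axis=0)  # (n_freqs, n_times)
    mask = (times >= baseline[0]) & (times < baseline[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    ref = power[:, mask].mean(axis=1, keepdims=True)
    return 10.0 * np.log10(power / ref)


def itpc(W: np.ndarray) -> np.ndarray:
    """Intertrial phase coherence from complex wavelet coefficients.

    ``ITPC(f,t) = | mean_trials exp(i arg W(f,t)) |``; 1 means the phase at
    that time-frequency point is identical on every trial.
    """
    phases = W / np.abs(W)
    return np.abs(phases.mean(axis=0))


def spectrogram(
    trials: Sequence[VmTrial],
    freqs: np.ndarray | None = None,
    db_baseline: tuple[float, float] = (2.5, 3.5),
) -> Spectrogram:
    """Trial-averaged wavelet power (raw and dB re baseline) plus ITPC.

    ``db_baseline`` is in seconds relative to stimulus onset.
    """
    W, f = wavelet_transform(trials, freqs=freqs)
    t = trials[0].times
    base_abs = (db_baseline[0] + trials[0].stim_onset, db_baseline[1] + trials[0].stim_onset)
    power = np.mean(np.abs(W) ** 2, axis=0)
    return Spectrogram(
        freqs=f,
        times=t,
        power=power,
        itpc=itpc(W),
        power_db=wavelet_power_db(W, t, base_abs),
    )


def detect_oscillation_trials(
    trials: Sequence[VmTrial],
    criterion: OscillationCriterion = OscillationCriterion(),
    baseline_mode: Literal["average", "per-trial"] = "average",
) -> tuple[np.ndarray, float]:
    """Flag oscillation trials and return (flags, oscillation probability).

    A trial is an oscillation trial when its response-window 4-7 Hz power
    exceeds ``ratio_threshold`` times the averaged baseline power. With the
    default ``baseline_mode="average"`` the denominator is the baseline band
    power averaged over the cell's trials; ``"per-trial"`` uses each trial's
    own baseline instead.
    """
    if not trials:
        raise ValueError("no trials")
    resp = np.array([band_power(t, criterion.band, criterion.response) for t in trials])
    base = np.array([band_power(t, criterion.band, criterion.baseline) for t in trials])
    if baseline_mode == "average":
        denom = np.full_like(base, base.mean())
    elif baseline_mode == "per-trial":
        denom = base
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, resp / denom, np.inf)
    flags = ratio > criterion.ratio_threshold
    return flags, float(flags.mean())
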