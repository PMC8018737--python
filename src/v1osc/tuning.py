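"""Orientation/direction selectivity and spike-phase analysis.

Selectivity indices follow the standard definitions

    OSI = (Rpref - Rorth) / (Rpref + Rorth)
    DSI = (Rpref - Ropp)  / (Rpref + Ropp)

estimated with a split-half resampling procedure: on each repetition the
trials of every direction are randomly split in half, the preferred
direction is taken from one half and the indices are computed from the
other half, so the preferred-direction choice never reuses the rates it is
evaluated on. Repetitions whose index falls outside [0, 1] (a negative
index, or an index inflated above 1 by a negative baseline-subtracted rate
at a non-preferred direction) indicate an unreliable preferred direction
and are discarded from that index's average.

Spike phases are measured against the 4-7 Hz component of the spike-removed
V_m via the Hilbert analytic signal; phase 0 is the oscillation peak and
negative angles are the rising phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .spectral import BandSpec, THETA_BAND, bandpass
from .traces import SpikeTrain, TUNING_WINDOWS, VmTrial, WindowSpec, remove_spikes

DIRECTIONS = tuple(range(0, 360, 30))  # the 12 drift directions, degrees


@dataclass
class TuningDataset:
    """Trials of one cell grouped by the 12 drift directions (30 deg apart)."""

    trials: dict[int, list[tuple[VmTrial, SpikeTrain]]]
    windows: WindowSpec = TUNING_WINDOWS
    cell_id: str = ""
    condition: str = ""
    true_osi: float | None = None
    true_dsi: float | None = None
    true_pref: float | None = None

    def __post_init__(self) -> None:
        if set(self.trials) != set(DIRECTIONS):
            raise ValueError("dataset must contain exactly the 12 directions 0,30,...,330")
        if any(len(v) < 2 for v in self.trials.values()):
            raise ValueError("every direction needs >= 2 trials for split-half resampling")

    @property
    def n_trials(self) -> int:
        return sum(len(v) for v in self.trials.values())


@dataclass
class SelectivityResult:
    osi: float
    dsi: float
    pref_direction: float
    n_valid_osi: int
    n_discarded_osi: int
    n_valid_dsi: int
    n_discarded_dsi: int


@dataclass
class PhaseSample:
    """Per-spike oscillation phase angles, radians in (-pi, pi].

    Convention: 0 = band peak, negative = rising phase, +/-pi = trough.
    """

    phases: np.ndarray
    direction_class: str = ""

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, float)
        if self.phases.size and (self.phases.min() <= -np.pi - 1e-12 or self.phases.max() > np.pi + 1e-12):
            raise ValueError("phases must lie in (-pi, pi]")

    def circular_mean(self) -> float:
        return float(np.angle(np.mean(np.exp(1j * self.phases))))


def osi(r_pref: float, r_orth: float) -> float:
    """Orientation selectivity index (Rpref - Rorth)/(Rpref + Rorth)."""
    if r_pref + r_orth == 0:
        raise ZeroDivisionError("OSI undefined: Rpref + Rorth = 0")
    return (r_pref - r_orth) / (r_pref + r_orth)


def dsi(r_pref: float, r_opp: float) -> float:
    """Direction selectivity index (Rpref - Ropp)/(Rpref + Ropp)."""
    if r_pref + r_opp == 0:
        raise ZeroDivisionError("DSI undefined: Rpref + Ropp = 0")
    return (r_pref - r_opp) / (r_pref + r_opp)


def _trial_rates(ds: TuningDataset) -> dict[int, np.ndarray]:
    """Baseline-subtracted response rate (Hz) of every trial, per direction."""
    out = {}
    (r0, r1), (b0, b1) = ds.windows.response, ds.windows.baseline
    for direction, pairs in ds.trials.items():
        rates = []
        for vm, spk in pairs:
            on = vm.stim_onset
            rates.append(spk.rate_in(on + r0, on + r1) - spk.rate_in(on + b0, on + b1))
        out[direction] = np.asarray(rates)
    return out


def split_half_selectivity(
    ds: TuningDataset, n_reps: int = 2000, seed: int | None = 0
) -> SelectivityResult:
    """Split-half resampled OSI/DSI estimate.

    Each repetition splits every direction's trials randomly into two halves
    (the extra trial of an odd count goes to half 1), takes the preferred
    direction as the argmax of half-1 mean rates (ties -> lowest direction
    index) and computes OSI/DSI from half-2 mean rates. Repetitions whose
    index is outside [0, 1] are discarded for that index. Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rates = _trial_rates(ds)
    dirs = np.array(DIRECTIONS)
    per_dir = [rates[d] for d in DIRECTIONS]

    osi_vals, dsi_vals = [], []
    pref_counts = np.zeros(12, dtype=int)
    for _ in range(n_reps):
        half1 = np.empty(12)
        half2 = np.empty(12)
        for i, r in enumerate(per_dir):
            perm = rng.permutation(r.size)
            n1 = (r.size + 1) // 2
            half1[i] = r[perm[:n1]].mean()
            half2[i] = r[perm[n1:]].mean()
        pref = int(np.argmax(half1))  # argmax returns the first (lowest) index on ties
        pref_counts[pref] += 1
        r_pref = half2[pref]
        r_opp = half2[(pref + 6) % 12]
        r_orth = 0.5 * (half2[(pref + 3) % 12] + half2[(pref + 9) % 12])
        if r_pref + r_orth != 0:
            v = osi(r_pref, r_orth)
            if 0.0 <= v <= 1.0:
                osi_vals.append(v)
        if r_pref + r_opp != 0:
            v = dsi(r_pref, r_opp)
            if 0.0 <= v <= 1.0:
                dsi_vals.append(v)

    if not osi_vals or not dsi_vals:
        raise ValueError("all repetitions discarded; selectivity undefined")
    return SelectivityResult(
        osi=float(np.mean(osi_vals)),
        dsi=float(np.mean(dsi_vals)),
        pref_direction=float(dirs[int(np.argmax(pref_counts))]),
        n_valid_osi=len(osi_vals),
        n_discarded_osi=n_reps - len(osi_vals),
        n_valid_dsi=len(dsi_vals),
        n_discarded_dsi=n_reps - len(dsi_vals),
    )


def preferred_direction(ds: TuningDataset) -> int:
    """Preferred direction (deg) from the full-data mean rates."""
    rates = _trial_rates(ds)
    means = np.array([rates[d].mean() for d in DIRECTIONS])
    return DIRECTIONS[int(np.argmax(means))]


def response_rates_by_class(ds: TuningDataset) -> tuple[float, float, float]:
    """Mean baseline-subtracted rates (Hz) at the preferred, opposite and
    orthogonal directions (orthogonal = average of the two +/-90 deg)."""
    rates = _trial_rates(ds)
    means = np.array([rates[d].mean() for d in DIRECTIONS])
    p = int(np.argmax(means))
    r_pref = means[p]
    r_opp = means[(p + 6) % 12]
    r_orth = 0.5 * (means[(p + 3) % 12] + means[(p + 9) % 12])
    return float(r_pref), float(r_opp), float(r_orth)


def direction_classes(pref_deg: int) -> dict[str, tuple[int, ...]]:
    """Map preferred/opposite/orthogonal labels to direction values (deg)."""
    i = DIRECTIONS.index(pref_deg % 360)
    return {
        "preferred": (DIRECTIONS[i],),
        "opposite": (DIRECTIONS[(i + 6) % 12],),
        "orthogonal": (DIRECTIONS[(i + 3) % 12], DIRECTIONS[(i + 9) % 12]),
    }


def spike_phases(
    trial: VmTrial,
    spikes: SpikeTrain,
    band: BandSpec = THETA_BAND,
    window: tuple[float, float] | None = None,
    direction_class: str = "",
    spike_removed: bool = False,
) -> PhaseSample:
    """Phase of each spike relative to the band-limited V_m oscillation.

    The spike-removed trace is bandpassed (zero-phase) to the 4-7 Hz band,
    the Hilbert analytic signal gives the instantaneous phase, and the phase
    is sampled at every spike time inside the response window (seconds
    relative to stimulus onset; None = whole trial).
    """
    vm = trial if spike_removed else remove_spikes(trial)
    bp = bandpass(vm.samples, band, vm.sampling_rate)
    phase = np.angle(hilbert(bp))
    times = spikes.times
    if window is not None:
        w0, w1 = (w + trial.stim_onset for w in window)
        times = times[(times >= w0) & (times < w1)]
    idx = np.clip(np.round(times * vm.sampling_rate).astype(int), 0, vm.samples.size - 1)
    return PhaseSample(phase[idx], direction_class)


def phase_histogram(
    sample: PhaseSample, n_bins: int = 36
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-integral density histogram of spike phases over (-pi, pi].

    Returns (bin_edges, density).
    """
    density, edges = np.histogram(
        sample.phases, bins=n_bins, range=(-np.pi, np.pi), density=True
    )
    return edges, density
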