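"""Ground-truth-labelled synthetic recordings.

Raw recordings of the study are not deposited, so every analysis stage is
exercised on synthetic data that reproduces the phenomenology the analyses
assume:

* naive trials - a broad stimulus-locked depolarization (alpha function)
  with a strong onset burst of firing followed by a smaller second peak;
* experienced trials - a damped ~5-Hz V_m oscillation lasting three to four
  cycles with fewer onset spikes that are instead phase-locked to the
  oscillation (von Mises phase density, centered on the rising phase);
* 12-direction tuning datasets whose ground-truth OSI/DSI follow in closed
  form from the noiseless rate map;
* double-exponential inward EPSCs with exactly known amplitude and 5%-rise
  latency.

Membrane noise is Gaussian, optionally 1/f-shaped (the default, since the
oscillation-trial criterion compares in-band powers and in-vivo V_m noise
is strongly low-frequency). Spikes are added as triangular transients of
fixed amplitude/width. All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .epsc import EpscTrial
from .traces import SpikeTrain, VmTrial
from .tuning import DIRECTIONS, TuningDataset


@dataclass(frozen=True)
class SynthVmParams:
    """Knobs of the membrane-potential trial generator.

    ``osc_*`` fields describe the experienced-condition damped oscillation
    (amplitude in mV, frequency in Hz, damping horizon in cycles);
    ``depol_amp``/``onset_rate`` the naive depolarization and onset burst;
    ``osc_locked_rate`` the oscillation-locked firing with a von Mises phase
    density centered at ``phase_lock_center`` (radians; negative = rising
    phase) of concentration ``phase_lock_kappa``.
    """

    condition: Literal["naive", "experienced"] = "experienced"
    resting_vm: float = -65.0  # mV
    noise_sd: float = 2.0  # mV
    noise_color: Literal["white", "pink"] = "pink"
    osc_freq: float = 5.0  # Hz
    osc_amp: float = 5.0  # mV
    osc_cycles: float = 3.5  # damping horizon, cycles
    depol_amp: float = 6.0  # mV (naive broad depolarization)
    onset_rate: float = 40.0  # Hz peak of the onset burst
    osc_locked_rate: float = 12.0  # Hz during the oscillation (experienced)
    phase_lock_center: float = -np.pi / 4  # rad, rising phase
    phase_lock_kappa: float = 2.0
    spike_amp: float = 60.0  # mV
    spike_width: float = 1.0  # ms
    sampling_rate: float = 10_000.0  # Hz
    stim_onset: float = 0.5  # s
    stim_dur: float = 0.2  # s
    trial_dur: float = 6.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 1000:
            raise ValueError("sampling_rate must be >= 1000 Hz")
        if not 0 < self.stim_onset < self.stim_onset + self.stim_dur < self.trial_dur:
            raise ValueError("need 0 < stim_onset < stim_onset + stim_dur < trial_dur")
        if self.osc_amp < 0 or self.noise_sd < 0:
            raise ValueError("osc_amp and noise_sd must be non-negative")


def naive_vm_params(**overrides) -> SynthVmParams:
    """Naive-condition defaults: depolarization + onset burst, no oscillation."""
    base = dict(condition="naive", osc_amp=0.0, osc_locked_rate=0.0,
                depol_amp=6.0, onset_rate=40.0)
    base.update(overrides)
    return SynthVmParams(**base)


def experienced_vm_params(**overrides) -> SynthVmParams:
    """Experienced-condition defaults: damped 5-Hz oscillation, reduced onset
    firing, oscillation-locked spikes."""
    base = dict(condition="experienced", osc_amp=5.0, depol_amp=1.5,
                onset_rate=10.0, osc_locked_rate=12.0)
    base.update(overrides)
    return SynthVmParams(**base)


@dataclass(frozen=True)
class SynthTuningParams:
    """Knobs of the 12-direction tuning generator.

    The evoked rate map over direction theta (deg) is

        R(theta) = base_rate + amp_rate * O(theta) * D(theta)
        O(theta) = exp(kappa_ori * (cos 2(theta - pref) - 1))     (orientation)
        D(theta) = (1 + dir_bias * cos(theta - pref)) / (1 + dir_bias)

    so the ground-truth OSI/DSI follow from evaluating R at the preferred,
    opposite and orthogonal directions.
    """

    pref_direction: float = 90.0  # deg, one of the 12
    base_rate: float = 3.0  # Hz evoked at all directions
    amp_rate: float = 30.0  # Hz tuned component at preferred
    kappa_ori: float = 1.5
    dir_bias: float = 0.6  # 0 = no direction preference, 1 = maximal
    n_trials_per_dir: int = 10
    condition: Literal["naive", "experienced"] = "experienced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.amp_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.dir_bias <= 1:
            raise ValueError("dir_bias must be in [0, 1]")
        if self.n_trials_per_dir < 2:
            raise ValueError("need >= 2 trials per direction")


@dataclass(frozen=True)
class SynthEpscParams:
    """Knobs of the light-evoked EPSC generator (double exponential)."""

    amplitude: float = 120.0  # pA, magnitude of the inward peak
    latency: float = 2.0  # ms: 5%-of-peak crossing after the TTL
    rise_tau: float = 0.8  # ms
    decay_tau: float = 6.0  # ms
    noise_sd: float = 3.0  # pA
    baseline_dur: float = 0.2  # s of pre-TTL trace
    post_dur: float = 0.2  # s after the TTL
    sampling_rate: float = 20_000.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude is a magnitude, must be >= 0")
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("need 0 < rise_tau < decay_tau")
        if self.latency < 0:
            raise ValueError("latency must be >= 0")


# ---------------------------------------------------------------------------
# V_m trials


def _noise(rng: np.random.Generator, n: int, sd: float, color: str, fs: float) -> np.ndarray:
    """Gaussian noise of SD ``sd``; 'pink' shapes the amplitude spectrum as
    1/sqrt(f) (power ~ 1/f) above 1 Hz, the dominant character of in-vivo
    V_m noise."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if color == "white":
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, 1.0))  # flat below 1 Hz
    shape[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * shape, n)
    return sd * shaped / shaped.std()


def _alpha(t: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak alpha function (t/tau) e^(1 - t/tau) for t >= 0."""
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (t[pos] / tau) * np.exp(1.0 - t[pos] / tau)
    return out


def _spike_template(spike_amp: float, spike_width: float, fs: float) -> np.ndarray:
    """Triangular AP transient: sharp rise to spike_amp, linear repolarization."""
    n = max(int(round(spike_width * 1e-3 * fs)), 3)
    n_up = max(n // 3, 1)
    up = np.linspace(0.0, spike_amp, n_up + 1)[1:]
    down = np.linspace(spike_amp, 0.0, n - n_up + 1)[1:-1]
    return np.concatenate([up, down])


def _add_spikes(samples: np.ndarray, spike_times: np.ndarray, fs: float,
                spike_amp: float, spike_width: float) -> None:
    """Add the AP template in place, peak aligned to each spike time."""
    if spike_times.size == 0 or spike_amp <= 0:
        return
    template = _spike_template(spike_amp, spike_width, fs)
    peak_off = int(np.argmax(template))
    for st in spike_times:
        i0 = int(round(st * fs)) - peak_off
        j0, j1 = max(i0, 0), min(i0 + template.size, samples.size)
        samples[j0:j1] += template[j0 - i0 : j1 - i0]


def _naive_spike_times(p: SynthVmParams, rng: np.random.Generator) -> np.ndarray:
    """Onset-locked inhomogeneous Poisson: main burst + smaller second peak."""
    if p.onset_rate == 0:
        return np.empty(0)
    tau = 0.05  # s, burst envelope
    t_max = p.stim_onset + 0.8
    grid = np.arange(p.stim_onset, t_max, 1e-3)
    env = _alpha(grid - p.stim_onset - 0.02, tau) + 0.35 * _alpha(
        grid - p.stim_onset - 0.27, tau
    )
    rate = p.onset_rate * env
    lam = rate.max()
    n_cand = rng.poisson(lam * (t_max - p.stim_onset))
    cand = np.sort(rng.uniform(p.stim_onset, t_max, n_cand))
    keep = rng.uniform(0, lam, cand.size) < np.interp(cand, grid, rate)
    return cand[keep]


def _experienced_spike_times(p: SynthVmParams, rng: np.random.Generator) -> np.ndarray:
    """Oscillation-phase-locked spikes: per cycle, a Poisson count following
    the damped envelope, phases drawn von Mises around phase_lock_center."""
    if p.osc_locked_rate == 0 or p.osc_freq <= 0:
        return np.empty(0)
    times = []
    n_cycles = int(math.ceil(p.osc_cycles)) + 2
    per_cycle = p.osc_locked_rate / p.osc_freq
    for c in range(n_cycles):
        mean_n = per_cycle * math.exp(-c / p.osc_cycles)
        n = rng.poisson(mean_n)
        if n == 0:
            continue
        phases = rng.vonmises(p.phase_lock_center, p.phase_lock_kappa, size=n)
        t = p.stim_onset + (c + phases / (2 * np.pi)) / p.osc_freq
        times.extend(t[t >= p.stim_onset])
    return np.sort(np.asarray(times))


def _enforce_refractory(times: np.ndarray, refractory_s: float = 0.005) -> np.ndarray:
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def generate_vm_trial(
    params: SynthVmParams, direction: float | None = None
) -> tuple[VmTrial, SpikeTrain]:
    """One membrane-potential trial plus its ground-truth spike train.

    trace = resting + noise + stimulus-evoked component + spike transients.
    The experienced evoked component is a decaying sinusoid at ``osc_freq``
    from stimulus onset (exponential envelope, time constant
    osc_cycles/osc_freq); the naive component is a broad alpha-function
    depolarization. Identical parameters (including seed) give bitwise-
    identical output.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    fs = p.sampling_rate
    n = int(round(p.trial_dur * fs))
    t = np.arange(n) / fs
    vm = p.resting_vm + _noise(rng, n, p.noise_sd, p.noise_color, fs)

    rel = t - p.stim_onset
    if p.condition == "experienced":
        if p.osc_amp > 0 and p.osc_freq > 0:
            env = np.exp(-np.maximum(rel, 0.0) * p.osc_freq / p.osc_cycles)
            vm += p.osc_amp * env * np.cos(2 * np.pi * p.osc_freq * rel) * (rel >= 0)
        if p.depol_amp > 0:
            vm += p.depol_amp * _alpha(rel, 0.15)
        spike_times = _experienced_spike_times(p, rng)
    else:
        if p.depol_amp > 0:
            vm += p.depol_amp * _alpha(rel, 0.12)
        spike_times = _naive_spike_times(p, rng)

    spike_times = _enforce_refractory(spike_times[spike_times < p.trial_dur - 0.01])
    _add_spikes(vm, spike_times, fs, p.spike_amp, p.spike_width)

    trial = VmTrial(
        samples=vm,
        sampling_rate=fs,
        stim_onset=p.stim_onset,
        stim_dur=p.stim_dur,
        direction=direction,
        condition=p.condition,
    )
    return trial, SpikeTrain(spike_times, trial.duration)


# ---------------------------------------------------------------------------
# tuning datasets


def tuning_rate_map(params: SynthTuningParams, directions=DIRECTIONS) -> np.ndarray:
    """Noiseless evoked rate (Hz) at each of the 12 directions."""
    th = np.deg2rad(np.asarray(directions, float) - params.pref_direction)
    ori = np.exp(params.kappa_ori * (np.cos(2 * th) - 1.0))
    dirf = (1.0 + params.dir_bias * np.cos(th)) / (1.0 + params.dir_bias)
    return params.base_rate + params.amp_rate * ori * dirf


def ground_truth_selectivity(params: SynthTuningParams) -> tuple[float, float]:
    """(OSI, DSI) from the noiseless rate map, by the index formulas."""
    rates = tuning_rate_map(params)
    p = int(np.argmax(rates))
    r_pref = rates[p]
    r_opp = rates[(p + 6) % 12]
    r_orth = 0.5 * (rates[(p + 3) % 12] + rates[(p + 9) % 12])
    osi_t = (r_pref - r_orth) / (r_pref + r_orth) if r_pref + r_orth else 0.0
    dsi_t = (r_pref - r_opp) / (r_pref + r_opp) if r_pref + r_opp else 0.0
    return float(osi_t), float(dsi_t)


def generate_tuning_dataset(
    params: SynthTuningParams, vm_params: SynthVmParams | None = None
) -> TuningDataset:
    """12 x n_trials_per_dir trials with stored ground-truth OSI/DSI.

    Evoked spikes are homogeneous Poisson over the response window at the
    rate-map rate of the trial's direction, added to the condition's V_m
    component; the baseline-subtracted trial rate is therefore an unbiased
    estimate of the map. Ground truth is computed from the noiseless map.
    """
    if vm_params is None:
        maker = experienced_vm_params if params.condition == "experienced" else naive_vm_params
        vm_params = maker(stim_dur=0.5)
    rates = tuning_rate_map(params)
    rng = np.random.default_rng(params.seed)
    resp = (0.05, 0.55)  # s after onset: the tuning response window
    trials: dict[int, list] = {}
    for d_i, direction in enumerate(DIRECTIONS):
        trials[direction] = []
        for _ in range(params.n_trials_per_dir):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            vp = replace(vm_params, seed=sub_seed, onset_rate=0.0, osc_locked_rate=0.0)
            vm, _spk = generate_vm_trial(vp, direction=direction)
            sub_rng = np.random.default_rng(sub_seed + 1)
            n_spk = sub_rng.poisson(rates[d_i] * (resp[1] - resp[0]))
            st = np.sort(
                sub_rng.uniform(vp.stim_onset + resp[0], vp.stim_onset + resp[1], n_spk)
            )
            # short absolute refractory: keeps thinning of high rates ~1%
            # so trial rates stay (near-)unbiased estimates of the map
            st = _enforce_refractory(st, 0.0015)
            _add_spikes(vm.samples, st, vp.sampling_rate, vp.spike_amp, vp.spike_width)
            trials[direction].append((vm, SpikeTrain(st, vm.duration)))
    osi_t, dsi_t = ground_truth_selectivity(params)
    return TuningDataset(
        trials=trials,
        condition=params.condition,
        true_osi=osi_t,
        true_dsi=dsi_t,
        true_pref=params.pref_direction,
    )


# ---------------------------------------------------------------------------
# EPSC trials


def _dexp(t_ms: np.ndarray, rise: float, decay: float) -> np.ndarray:
    out = np.zeros_like(t_ms)
    pos = t_ms >= 0
    out[pos] = np.exp(-t_ms[pos] / decay) - np.exp(-t_ms[pos] / rise)
    return out


def dexp_peak_time(rise: float, decay: float) -> float:
    """Analytic peak time (ms) of exp(-t/decay) - exp(-t/rise)."""
    return math.log(decay / rise) * rise * decay / (decay - rise)


def dexp_5pct_time(rise: float, decay: float) -> float:
    """Time (ms) at which the rising double exponential reaches 5% of peak."""
    from scipy.optimize import brentq

    tp = dexp_peak_time(rise, decay)
    gp = math.exp(-tp / decay) - math.exp(-tp / rise)
    return brentq(
        lambda t: (math.exp(-t / decay) - math.exp(-t / rise)) - 0.05 * gp, 1e-9, tp
    )


def generate_epsc_trial(params: SynthEpscParams) -> tuple[EpscTrial, SynthEpscParams]:
    """One voltage-clamp sweep with a known inward double-exponential EPSC.

    The waveform is scaled so the inward peak magnitude equals ``amplitude``
    and shifted so the 5%-of-peak crossing occurs exactly ``latency`` ms
    after the TTL (which sits at ``baseline_dur`` seconds into the sweep).
    Returns the trial and the parameters as its ground truth.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    fs = p.sampling_rate
    n = int(round((p.baseline_dur + p.post_dur) * fs))
    t_ms = (np.arange(n) / fs - p.baseline_dur) * 1e3  # ms after TTL
    current = p.noise_sd * rng.standard_normal(n) if p.noise_sd else np.zeros(n)
    if p.amplitude > 0:
        tp = dexp_peak_time(p.rise_tau, p.decay_tau)
        gp = math.exp(-tp / p.decay_tau) - math.exp(-tp / p.rise_tau)
        t0 = p.latency - dexp_5pct_time(p.rise_tau, p.decay_tau)
        current -= (p.amplitude / gp) * _dexp(t_ms - t0, p.rise_tau, p.decay_tau)
    trial = EpscTrial(current=current, sampling_rate=fs, ttl_time=p.baseline_dur)
    return trial, p


# ---------------------------------------------------------------------------
# populations


@dataclass
class SynthCell:
    """One synthetic cell: its trials plus the parameters that made them."""

    cell_id: str
    condition: str
    vm_params: SynthVmParams
    trials: list[tuple[VmTrial, SpikeTrain]]


def generate_cell_population(
    condition: Literal["naive", "experienced"],
    n_cells: int,
    seed: int = 0,
    n_trials: int = 40,
    **overrides,
) -> list[SynthCell]:
    """Population of cells with per-cell jittered parameters.

    Cell-to-cell variability: oscillation amplitude, depolarization and
    firing rates jittered lognormally (~20% CV) around the condition
    defaults. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    maker = experienced_vm_params if condition == "experienced" else naive_vm_params
    cells = []
    for c in range(n_cells):
        base = maker(**overrides)
        jit = lambda: float(np.exp(rng.normal(0.0, 0.2)))
        p = replace(
            base,
            osc_amp=base.osc_amp * jit(),
            depol_amp=base.depol_amp * jit(),
            onset_rate=base.onset_rate * jit(),
            osc_locked_rate=base.osc_locked_rate * jit(),
        )
        trials = []
        for k in range(n_trials):
            tp = replace(p, seed=int(rng.integers(0, 2**31 - 1)))
            vm, spk = generate_vm_trial(tp)
            vm.cell_id = f"{condition}_{c:03d}"
            vm.trial_id = f"t{k:03d}"
            trials.append((vm, spk))
        cells.append(SynthCell(f"{condition}_{c:03d}", condition, p, trials))
    return cells
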