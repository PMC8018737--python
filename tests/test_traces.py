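"""Spike removal, spike detection, PSTH and V_m window statistics."""

import numpy as np
import pytest

from v1osc import synth, traces
from v1osc.traces import (
    FAMILIARITY_WINDOWS,
    Psth,
    SpikeTrain,
    VmTrial,
    WindowSpec,
    baseline_subtracted_rate,
    compute_psth,
    delta_vm_peaks,
    detect_spikes,
    remove_spikes,
    zscore_rate,
)


def flat_trial(value=0.0, fs=20_000.0, dur=2.0, onset=0.5, stim=0.2):
    return VmTrial(np.full(int(dur * fs), value), fs, onset, stim)


class TestRemoveSpikes:
    def test_constant_trace_unchanged(self):
        t = flat_trial(value=-65.0)
        assert np.array_equal(remove_spikes(t).samples, t.samples)

    def test_monotone_ramp_interior_unchanged(self):
        fs = 1000.0
        t = VmTrial(np.linspace(0, 10, 2000), fs, 0.5, 0.2)
        out = remove_spikes(t, window_ms=12.5)
        half = 13 // 2 + 1
        assert np.allclose(out.samples[half:-half], t.samples[half:-half])

    def test_narrow_spike_removed(self):
        # 2-ms, 50-mV spike on a flat baseline: residual < 1 mV after the
        # 12.5-ms median
        fs = 20_000.0
        x = np.zeros(int(0.5 * fs))
        i0 = 5000
        w = int(0.002 * fs)
        x[i0 : i0 + w] = 50.0
        t = VmTrial(x, fs, 0.1, 0.2)
        out = remove_spikes(t)
        assert np.max(np.abs(out.samples)) < 1.0

    def test_matches_naive_sliding_median(self):
        # oracle: brute-force sliding median with edge replication
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(50, 200))
            x = rng.normal(size=n)
            fs = 1000.0
            t = VmTrial(x, fs, 0.01, 0.01)
            win_ms = float(rng.uniform(3, 15))
            out = remove_spikes(t, window_ms=win_ms)
            k = int(np.ceil(win_ms * 1e-3 * fs))
            if k % 2 == 0:
                k += 1
            k = max(k, 3)
            half = k // 2
            padded = np.r_[np.repeat(x[0], half), x, np.repeat(x[-1], half)]
            expected = np.array([np.median(padded[i : i + k]) for i in range(n)])
            assert np.allclose(out.samples, expected)

    def test_window_longer_than_trace_raises(self):
        t = VmTrial(np.zeros(100), 1000.0, 0.01, 0.01)
        with pytest.raises(ValueError):
            remove_spikes(t, window_ms=200.0)


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        assert detect_spikes(flat_trial()).times.size == 0

    def test_recovers_ground_truth_spikes(self):
        # every generated spike found within 0.5 ms, no false positives
        vm, gt = synth.generate_vm_trial(synth.naive_vm_params(seed=3, noise_sd=1.0))
        det = detect_spikes(vm)
        assert det.times.size == gt.times.size
        assert np.all(np.abs(det.times - gt.times) <= 5e-4)

    def test_subthreshold_bump_ignored(self):
        # a 10-mV, 50-ms-wide depolarization is slow: the fine-coarse
        # difference stays below the 15-mV threshold
        fs = 20_000.0
        t = np.arange(int(2 * fs)) / fs
        x = 10.0 * np.exp(-0.5 * ((t - 1.0) / 0.02) ** 2)
        trial = VmTrial(x, fs, 0.5, 0.2)
        assert detect_spikes(trial).times.size == 0

    def test_translation_equivariance(self):
        vm, _ = synth.generate_vm_trial(synth.naive_vm_params(seed=5))
        base = detect_spikes(vm).times
        k = 1000  # samples; spikes stay far from the trace edges
        shifted = VmTrial(
            np.roll(vm.samples, k), vm.sampling_rate, vm.stim_onset, vm.stim_dur
        )
        out = detect_spikes(shifted).times
        assert out.size == base.size
        assert np.allclose(out, base + k / vm.sampling_rate, atol=2e-4)

    def test_nonfinite_raises(self):
        trial = flat_trial()
        trial.samples[5] = np.nan
        with pytest.raises(ValueError):
            detect_spikes(trial)


class TestPsth:
    def test_no_spikes_all_zero(self):
        trains = [SpikeTrain(np.empty(0), 2.0) for _ in range(5)]
        psth = compute_psth(trains)
        assert np.all(psth.rate == 0) and np.all(psth.normalized_rate == 0)

    def test_single_bin_rate(self):
        # 10 trials, one spike each at 0.105 s -> bin [0.10, 0.11) = 100 Hz
        trains = [SpikeTrain(np.array([0.105]), 2.0) for _ in range(10)]
        psth = compute_psth(trains)
        b = int(0.105 / 0.01)
        assert psth.rate[b] == pytest.approx(100.0)
        assert psth.rate.sum() == pytest.approx(100.0)

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        trains = [
            SpikeTrain(np.sort(rng.uniform(0, 2.0, rng.integers(0, 50))), 2.0)
            for _ in range(7)
        ]
        psth = compute_psth(trains)
        total = sum(t.times.size for t in trains)
        binw = np.diff(psth.bin_edges)
        assert np.sum(psth.rate * binw) * len(trains) == pytest.approx(total)

    def test_poisson_rate_recovered(self):
        # stationary 20-Hz Poisson, 200 trials: smoothed rate within 10%
        rng = np.random.default_rng(1)
        trains = []
        for _ in range(200):
            n = rng.poisson(20 * 2.0)
            trains.append(SpikeTrain(np.sort(rng.uniform(0, 2.0, n)), 2.0))
        psth = compute_psth(trains)
        interior = psth.smoothed_rate[15:-15]
        assert np.all(np.abs(interior - 20.0) < 2.0)


class TestRates:
    def test_stationary_train_near_zero(self):
        rng = np.random.default_rng(2)
        trains = [
            SpikeTrain(np.sort(rng.uniform(0, 6.0, rng.poisson(60))), 6.0)
            for _ in range(50)
        ]
        val = baseline_subtracted_rate(trains, FAMILIARITY_WINDOWS, stim_onset=0.5)
        assert abs(val) < 1.5

    def test_response_only_spikes(self):
        trains = [SpikeTrain(np.array([0.6, 0.65]), 6.0) for _ in range(4)]
        val = baseline_subtracted_rate(trains, FAMILIARITY_WINDOWS, stim_onset=0.5)
        assert val == pytest.approx(2 / 0.2)

    def test_experienced_fires_less_than_naive(self):
        naive = [
            synth.generate_vm_trial(synth.naive_vm_params(seed=s))[1] for s in range(15)
        ]
        exp = [
            synth.generate_vm_trial(synth.experienced_vm_params(seed=s))[1]
            for s in range(15)
        ]
        r_naive = baseline_subtracted_rate(naive, FAMILIARITY_WINDOWS, stim_onset=0.5)
        r_exp = baseline_subtracted_rate(exp, FAMILIARITY_WINDOWS, stim_onset=0.5)
        assert r_exp < r_naive


class TestZscore:
    def _psth(self, rate):
        edges = np.arange(0, len(rate) * 0.01 + 0.005, 0.01)
        return Psth(edges, rate, rate, rate / max(rate.max(), 1), 1)

    def test_constant_equal_to_baseline_is_zero(self):
        rng = np.random.default_rng(3)
        rate = 10.0 + rng.normal(0, 1, 600)
        psth = self._psth(rate)
        z = zscore_rate(psth, (3.0, 6.0))
        mask = (psth.bin_centers >= 3.0) & (psth.bin_centers < 6.0)
        assert z[mask].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_baseline_sd_raises(self):
        psth = self._psth(np.full(600, 5.0))
        with pytest.raises(ValueError):
            zscore_rate(psth, (3.0, 6.0))

    def test_onset_peak_has_max_z(self):
        rng = np.random.default_rng(4)
        rate = 2.0 + rng.normal(0, 0.5, 600)
        rate[55] = 50.0
        psth = self._psth(rate)
        z = zscore_rate(psth, (3.0, 6.0))
        assert int(np.argmax(z)) == 55


class TestDeltaVm:
    def test_flat_trace_zero(self):
        t = flat_trial(value=-60.0, dur=6.0)
        assert delta_vm_peaks(t) == pytest.approx((0.0, 0.0, 0.0))

    def test_cosine_peaks_equal_amplitude(self):
        # 5-Hz cosine from onset: each 0.2-s window contains a full peak
        fs = 10_000.0
        t = np.arange(int(6.0 * fs)) / fs
        rel = t - 0.5
        x = np.where(rel >= 0, 4.0 * np.cos(2 * np.pi * 5 * rel), 0.0)
        x[t >= 3.0] = 0.0  # zero-mean baseline region
        trial = VmTrial(x, fs, 0.5, 0.2)
        peaks = delta_vm_peaks(trial)
        assert peaks == pytest.approx((4.0, 4.0, 4.0), abs=0.01)

    def test_naive_first_window_dominates(self):
        vm, _ = synth.generate_vm_trial(
            synth.naive_vm_params(seed=11, noise_sd=0.0, onset_rate=0.0)
        )
        peaks = delta_vm_peaks(vm)
        assert peaks[0] > peaks[2]
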