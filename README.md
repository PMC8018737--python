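# v1osc

Analysis toolkit for familiarity-induced ~5-Hz membrane-potential
oscillations in mouse primary visual cortex (V1), and the ring-network rate
model with adaptation that explains them.

After a few days of passive exposure to a grating stimulus, V1 layer-2/3
neurons respond to the now-familiar stimulus with a damped ~5-Hz oscillation
of the membrane potential (V_m), fewer onset spikes that phase-lock to the
oscillation, and sharper orientation/direction tuning. This package
implements, for in-vivo whole-cell recordings:

- **Trace processing** — action-potential removal (12.5-ms running median),
  AP detection (fine/coarse Hanning smoothing difference, 15-mV threshold),
  PSTHs (10-ms bins, 200-ms/40-ms-σ Gaussian smoothing), baseline-subtracted
  rates and V_m peak windows.
- **Spectral analysis** — FFT power spectra, band magnitudes (zero-phase
  Butterworth bandpass + Hilbert envelope) for the 4–7 / 8–12 / 13–30 Hz
  bands, complex Morlet wavelet time–frequency maps (40 log-spaced
  frequencies 2–80 Hz, 3→10 cycles), intertrial phase coherence (ITPC),
  and the oscillation-trial detector (response-window 4–7 Hz power > 10×
  the averaged baseline power).
- **Tuning** — orientation and direction selectivity with split-half
  resampling,

      OSI = (R_pref − R_orth) / (R_pref + R_orth)
      DSI = (R_pref − R_opp)  / (R_pref + R_opp)

  where each of 2000 repetitions picks the preferred direction from one
  random half of the trials and evaluates the indices on the other half;
  plus spike-phase extraction against the 4–7 Hz V_m component (Hilbert
  phase; 0 = oscillation peak, negative = rising flank).
- **EPSC features** — amplitude, 5%-rise latency and peak time of
  optogenetically evoked inward currents, with monosynaptic (<3.5 ms) and
  access-resistance (≤60 MΩ) quality filters.
- **Ring model** — populations indexed by preferred direction φ ∈ (−π, π]
  with threshold-linear rate dynamics and slow adaptation,

      τ_r dr/dt = −r + f( ∫ J(φ−φ′) r(φ′) dφ′ + i(φ,t) − k a )
      τ_a da/dt = −a + r,          f(x) = max(x, 0)

  J(Δφ) = J_E exp(−Δφ²/σ_E²) − J_I exp(−Δφ²/σ_I²), feedforward drive
  i(φ,t) separable into two Gaussian bumps (stimulus direction and its
  opposite) times a low-pass-filtered 500-ms pulse. Learning is a parameter
  switch: feedforward gain γ₀ 1 → 0.5 and recurrent profile flat-weak
  (J_E = 0.15, σ_E = ∞) → local excitation with global inhibition
  (J_E = 3, σ_E = π/6, J_I = 1, σ_I = ∞). Integration is fixed-step RK4.
- **Synthetic data** — ground-truth-labelled V_m trials, 12-direction
  tuning datasets and EPSC sweeps emulating both conditions, so the whole
  pipeline is testable without raw recordings.

## Worked example

```python
from v1osc import ring, spectral, synth, traces, tuning

post = ring.simulate(ring.post_learning_params())
pre = ring.simulate(ring.pre_learning_params())
print(ring.dominant_frequency(post, window=(500, 1500)))   # 4.58 (Hz)
print(ring.model_selectivity(pre))    # ratio 3.50, population mean 0.1185
print(ring.model_selectivity(post))   # ratio 4.94, population mean 0.0688

vm, spikes = synth.generate_vm_trial(synth.experienced_vm_params(seed=0))
clean = traces.remove_spikes(vm)
flags, prob = spectral.detect_oscillation_trials([clean])
spectral.band_magnitude(clean, spectral.THETA_BAND, window=(0.0, 0.5))
# 7 spikes; 4-7 Hz magnitude 3.01 mV; oscillation trial: True

ds = synth.generate_tuning_dataset(synth.SynthTuningParams(n_trials_per_dir=20, seed=5))
res = tuning.split_half_selectivity(ds, n_reps=2000, seed=0)
# ground truth OSI=0.787 DSI=0.517 -> estimate OSI=0.790 DSI=0.526
```

The post-learning network oscillates at ~5 Hz at the stimulated direction
(4.58 Hz spectral peak), its preferred/opposite rate ratio rises from 3.50
to 4.94 while the population-mean rate drops by ~40% — sharper selectivity
with fewer spikes — and orthogonal-direction populations are suppressed to
exactly zero by the firing threshold. On the synthetic experienced trial
the detector flags the damped 5-Hz V_m oscillation (3 mV 4–7 Hz magnitude
against a ~0.5 mV baseline), and the split-half estimator recovers the
generator's ground-truth selectivity to ±0.01.

## Command line

```
v1osc synth --condition experienced --n-cells 5 --seed 1 --out data/
v1osc analyze-familiarity --container data/ --out report/
v1osc analyze-tuning --container data/ --out report/
v1osc epsc --container epsc_data/ --out report/
v1osc simulate --phase post --out post.h5
```

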