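# Methods

## Scope and data model

The package analyses trial-structured in-vivo whole-cell recordings from
mouse V1: current-clamp membrane-potential sweeps (`VmTrial`, mV) with
stimulus metadata, detected action-potential times (`SpikeTrain`, s), trials
grouped by the 12 grating drift directions (`TuningDataset`), and
voltage-clamp sweeps with a light-pulse TTL (`EpscTrial`, pA). All times are
seconds from trial start; analysis windows are half-open `[start, end)` and
specified relative to stimulus onset; directions are degrees at interfaces
and radians internally. Raw recordings from the original experiments are not
publicly deposited, so a synthetic generator (below) provides
ground-truth-labelled data for every stage.

## Trace processing

**Spike removal** is a 12.5-ms running median (window rounded up to an odd
sample count, edges replicated). Edge replication avoids fabricating onset
transients; the median passes the subthreshold V_m unchanged wherever it is
locally monotone over the window.

**Spike detection** convolves the raw trace with unit-sum Hanning windows of
0.5 ms and 500 ms and thresholds the difference at 15 mV. The unit-sum
normalization keeps both smoothed traces in mV so the threshold has physical
meaning; the coarse trace estimates the slow V_m fluctuation, making the
difference a high-pass amplitude estimate. One spike is emitted per
contiguous supra-threshold run, at the run's maximum (earliest sample on
ties — the tie-break is arbitrary but deterministic).

**PSTHs** use 10-ms bins, `rate = count / (n_trials × bin width)`, smoothed
with a truncated unit-sum Gaussian (200-ms support, 40-ms σ). Two
normalizations are provided because heat-map and average-trace displays use
different ones: `normalized_rate` divides the smoothed rate by its per-cell
maximum (so tuning-curve displays peak at ~1), and `zscore_rate` references
a baseline window mean/SD. The z-scoring window is a configuration option;
default baseline windows are 2.5–4.7 s post-onset (200-ms stimulus,
response 0.05–0.25 s) and 2.5–3.5 s (500-ms stimulus, response 0.05–0.55 s).

**ΔV_m peaks** take the maximum of the spike-removed V_m in windows
I (0.05–0.25 s), II (0.25–0.45 s), III (0.45–0.65 s) after onset — one per
cycle of a 5-Hz oscillation — minus the mean baseline V_m.

## Spectral analysis

Power spectra are one-sided FFT periodograms of mean-subtracted windows.
Band magnitudes apply a zero-phase (forward–backward) 4th-order Butterworth
bandpass and average the Hilbert-envelope amplitude over the window; for an
in-band sinusoid of amplitude A this reports A (mV), which makes band
magnitudes comparable across bands and cells. Zero-phase filtering is
required because spike phases are read off the same filtered signal.

The wavelet transform uses complex Morlet kernels on 40 log-spaced
frequencies from 2 to 80 Hz with cycle counts mapped linearly from 3 to 10
across the grid (only the range is prescribed by the source analyses; the
linear map is the simplest monotone choice). Gaussian envelopes are
normalized to unit sum; traces are reflect-padded by the longest kernel
half-length. Trial-averaged power can be expressed in dB relative to the
mean power of a baseline window per frequency (default 2.5–3.5 s
post-onset, configurable — display normalization only). ITPC is the
magnitude of the across-trial mean unit phase vector,
`|mean exp(i·arg W)|` ∈ [0, 1]; for n independent phases its expectation is
≈ √(π/4n), which the tests use as the null scale.

**Oscillation-trial detector.** A trial is an oscillation trial when its
response-window (onset to +0.5 s) 4–7 Hz band power exceeds 10× the
averaged baseline (4.5–5.0 s post-onset) band power. "Power" is the mean
squared amplitude of the bandpassed signal; the ratio is scale-free, so
this choice only shifts the effective threshold, which is exposed in the
configuration. The denominator defaults to the baseline power averaged
across the cell's trials (`baseline_mode="average"`); with per-trial
denominators (`"per-trial"`) the ratio of two short-window power estimates
has heavy F-like tails and a materially higher false-positive rate on
stationary data. Manual inspection of flagged trials, part of the original
workflow, is inherently not reproducible and is omitted.

## Selectivity and spike phases

Per-trial rates are baseline-subtracted (response 0.05–0.55 s, baseline
2.5–3.5 s post-onset), so they can be negative. Each split-half repetition
permutes every direction's trials, assigns the extra trial of an odd count
to half 1, takes the preferred direction as the argmax of half-1 mean rates
(ties → lowest direction index), and computes OSI/DSI from half-2 rates,
with the orthogonal rate the average of the two ±90° directions. A
repetition whose index falls outside [0, 1] is discarded for that index
(independently for OSI and DSI): a negative index, or an index pushed above
1 by a negative non-preferred rate, both signal an unreliable preferred
direction. The estimate is the mean over valid repetitions (default 2000),
deterministic under the seed. Whether the preferred-direction argmax should
use smoothed rates is unknowable from the source description; raw
baseline-subtracted means are the default.

The truncation makes the null (untuned cell) estimate small but positive —
the tests bound it with an independently coded brute-force oracle rather
than pretending it is zero.

Spike phases are the Hilbert-analytic-signal angle of the 4–7 Hz bandpassed,
spike-removed V_m, sampled at spike times in the response window. For a
cosine, phase 0 is the peak, −π/2 the steepest rise, ±π the trough. Phase
tables are emitted per spike so that either per-cell or pooled group
statistics can be formed downstream.

## EPSC extraction

The baseline is the mean current over 0.2 s before the TTL. The peak is the
most negative baseline-subtracted sample in (0, 40] ms after the TTL
(EPSCs are inward; amplitude is reported as a positive magnitude). The
latency is the first post-TTL crossing of 5% of the amplitude, searched up
to the peak. A deflection below 3× the baseline SD counts as "no response"
(amplitude 0, latency undefined) — the original reports responsive versus
non-responsive cells without a printed criterion, so the floor is explicit
and configurable. Cell-level features come from the 10-trial average trace.
QC keeps cells with mean latency < 3.5 ms (monosynaptic) and access
resistance ≤ 60 MΩ. Membrane resistance is the least-squares slope of
steady-state V against injected I (mV/pA = GΩ, reported in MΩ).

## Ring model

N populations at directions uniformly covering (−π, π] evolve under

    τ_r dr/dt = −r + f(Σ_j J(φ_i − φ_j) r_j Δφ + i(φ_i, t) − k a_i),
    τ_a da/dt = −a + r,    f(x) = max(x, 0),    Δφ = 2π/N,

with wrapped angular distances in the Gaussian connectivity (the printed
kernels are non-periodic; wrapping is the standard ring reading and only
affects the tails). σ = ∞ is an explicit sentinel meaning a constant kernel
term, never a numeric overflow. Fixed parameters: τ_r = 5 ms, τ_a = 150 ms,
τ_ext = 50 ms, t_stim = 500 ms, k = 1, σ_stim = π/10, γ₁ = 0.2. Learning
switches (γ₀, J_E, σ_E, J_I, σ_I) from (1, 0.15, ∞, 0, –) to
(0.5, 3, π/6, 1, ∞). The temporal drive is the exact exponential response
of a τ_ext low-pass to the stimulus boxcar, evaluated analytically at every
RK4 stage time.

Integration is classical fixed-step RK4 from r = a = 0. Discretization
defaults are the package's own (the source states none): N = 180,
t_total = 2000 ms, stimulus onset 500 ms, dt = 0.05 ms. dt is deliberately
below the τ_r-stability scale because the threshold nonlinearity reduces
RK4's local order at threshold crossings: the dt-halving self-convergence
error is 2.8×10⁻⁷ relative sup-norm at dt = 0.05 ms versus 1.5×10⁻⁶ at
0.1 ms. Doubling N changes stimulus-window mean rates by <0.1%. A rate
exceeding 10⁶ raises an instability error naming dt and the parameters.

Readouts: dominant frequency is the Hann-windowed, linearly detrended
periodogram peak (zero-padded to ≤0.25 Hz resolution, frequencies ≥0.5 Hz)
of one population's time course — nan for near-constant series; selectivity
is the time-averaged rate at the stimulated and opposite directions over
the stimulus window with their ratio (nan when the opposite rate is zero)
and the population mean; displayed rates and net inputs are normalized by
the post-learning maximum. With the post-learning set the preferred
direction oscillates at ≈4.6 Hz, the opposite direction in anti-phase
(net-input cross-spectral phase ≈ −2.84 rad), orthogonal populations are
thresholded to zero while their *net input* still oscillates at the common
frequency — the model's account of why subthreshold V_m oscillates at all
directions while firing does not.

## Synthetic data

The generator emulates the phenomenology the analyses assume, with exact
ground truth:

- **Experienced V_m**: damped cosine at 5 Hz from stimulus onset, amplitude
  5 mV, exponential envelope with time constant osc_cycles/osc_freq
  (default 3.5 cycles — the "three to four cycles" phenomenology); spikes
  phase-locked via a von Mises density (center −π/4, the rising flank;
  κ = 2) with per-cycle Poisson counts following the envelope.
- **Naive V_m**: alpha-function depolarization (6 mV) and an onset burst
  (inhomogeneous Poisson, 40 Hz peak, with a smaller second peak) —
  strong onset firing, no oscillation.
- **Noise**: Gaussian, by default 1/f-shaped above 1 Hz at 2 mV SD. The
  colored default matters: the oscillation-trial criterion compares in-band
  powers, and white noise would make the baseline 4–7 Hz power unrealistically
  tiny, flagging any stimulus transient. Spikes are triangular 60-mV, 1-ms
  transients with a 5-ms refractory (1.5 ms in tuning datasets, where rate
  fidelity matters more than waveform realism: dead-time thinning of a
  33-Hz rate is ~9% at 3 ms but ~1.5% at 1.5 ms, and would bias the rate
  map the ground truth is computed from).
- **Tuning**: evoked rate map `R(θ) = base + amp·O(θ)·D(θ)` with a von
  Mises orientation factor and a cosine direction-bias factor; ground-truth
  OSI/DSI are the index formulas evaluated on the noiseless map. Defaults
  (base 3 Hz, peak ~33 Hz over the 0.5-s response window, 10 trials per
  direction) describe a strongly responsive awake V1 cell; evoked spikes
  are uniform Poisson over the response window so the baseline-subtracted
  trial rate estimates the map without bias.
- **EPSC**: difference of exponentials (rise 0.8 ms, decay 6 ms), scaled to
  the target peak magnitude and time-shifted so the analytic 5%-of-peak
  crossing lands exactly at the target latency (solved with a bracketing
  root-finder at generation time).
- **Populations**: per-cell lognormal jitter (~20% CV) of amplitudes and
  rates around the condition defaults. Trial counts per cell default to 40
  (10 per direction for tuning) — configurable, since the original
  per-cell counts are not reported.

Everything is deterministic under the seed, bitwise.

What the synthetic data does *not* contain: arousal/eye-movement covariates,
cell-to-cell waveform variability, electrode drift, up/down-state
structure, or conductance-based membrane dynamics. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
assumptions, not robustness to every artifact of real awake recordings.

## Reporting layer

The directory container stores a versioned `manifest.json` plus one
`time_s,value` CSV per trial (12 significant digits; round-trips to ~1e-12
relative). Pipelines emit per-cell CSV tables and group summaries
(two-sided Mann–Whitney U, Benjamini–Hochberg correction within each
table); every number in a report is produced by exactly one module
operation. Reports are byte-identical across reruns for a fixed container,
configuration and seed.

## Numerical and edge-case conventions

- Windows half-open; 0-based sample indexing; window bounds rounded to the
  nearest sample.
- Butterworth filters: order 4, zero-phase via `sosfiltfilt`.
- Bandpass magnitude is invariant to DC offsets by construction.
- Degenerate inputs raise rather than return silently: zero baseline SD in
  z-scoring, zero index denominators, all repetitions discarded, windows
  outside the trial, non-finite samples, unstable dt.
- ITPC of a single trial is exactly 1 (a degenerate but well-defined case).

## Problem sizes used in the test suite

The suite exercises the full default discretization for the model
(N = 180, dt = 0.05 ms, 2 s) and scaled-down populations elsewhere
(typically 2–5 cells × 4–40 trials, 100–2000 resampling repetitions,
1000 trials for detector operating points) — sizes chosen to estimate each
statistic to well within its test tolerance.
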