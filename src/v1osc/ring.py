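"""Ring-attractor firing-rate model with slow adaptation.

A one-dimensional ring of neuronal populations indexed by preferred drift
direction phi in (-pi, pi] evolves as

    tau_r dr/dt = -r + f( (J * r)(phi) + i(phi, t) - k a(phi, t) )
    tau_a da/dt = -a + r

with threshold-linear f(x) = max(x, 0), Gaussian difference-of-kernels
recurrent connectivity J(dphi) = J_E exp(-dphi^2/sigma_E^2)
- J_I exp(-dphi^2/sigma_I^2) (sigma = inf meaning a constant profile), and
separable feedforward drive i(phi, t) = i_s(phi) i_t(t): two Gaussian bumps
at the stimulus direction phi0 and its opposite (relative weight gamma1),
times a boxcar of duration t_stim low-pass filtered with tau_ext.

Visual experience is modelled as a parameter change: before learning the
recurrent profile is weak and flat and the feedforward gain is high; after
learning recurrent connections become strong local excitation with global
inhibition while the feedforward gain halves. With the post-learning set the
interaction of recurrent positive feedback and slow adaptation produces a
~5 Hz rate oscillation at the stimulated direction, anti-phase at the
opposite direction, with orthogonal populations suppressed below threshold.

Integration is fixed-step classical Runge-Kutta (RK4) from r = a = 0; the
ring integral is a Riemann sum with weight 2*pi/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

INF = float("inf")  # sigma sentinel: constant (all-to-all) kernel term


@dataclass(frozen=True)
class RingModelParams:
    """Model parameters. Times in ms, angles in radians, gains unitless."""

    tau_r: float = 5.0
    tau_a: float = 150.0
    tau_ext: float = 50.0
    t_stim: float = 500.0
    k: float = 1.0
    sigma_stim: float = np.pi / 10
    gamma1: float = 0.2
    gamma0: float = 1.0
    J_E: float = 0.15
    sigma_E: float = INF
    J_I: float = 0.0
    sigma_I: float = INF
    phi0: float = 0.0
    N: int = 180
    dt: float = 0.05
    t_total: float = 2000.0
    stim_onset: float = 500.0

    def __post_init__(self) -> None:
        if min(self.tau_r, self.tau_a, self.tau_ext) <= 0:
            raise ValueError("time constants must be positive")
        if self.N < 8:
            raise ValueError("need N >= 8 ring populations")
        if self.dt > self.tau_r / 5:
            raise ValueError("dt must be <= tau_r/5 for a stable RK4 step")
        for s in (self.sigma_E, self.sigma_I, self.sigma_stim):
            if not s > 0:
                raise ValueError("sigma values must be positive (inf allowed)")


def pre_learning_params(**overrides) -> RingModelParams:
    """Parameter set for the naive network (flat weak recurrence)."""
    base = dict(gamma0=1.0, J_E=0.15, sigma_E=INF, J_I=0.0, sigma_I=INF)
    base.update(overrides)
    return RingModelParams(**base)


def post_learning_params(**overrides) -> RingModelParams:
    """Parameter set after visual experience (local excitation, global
    inhibition, halved feedforward gain)."""
    base = dict(gamma0=0.5, J_E=3.0, sigma_E=np.pi / 6, J_I=1.0, sigma_I=INF)
    base.update(overrides)
    return RingModelParams(**base)


@dataclass
class RingModelResult:
    """Simulated fields over direction x time.

    ``r``/``a``/``x`` have shape (N, n_times): firing rate, adaptation and
    net input (the argument of the threshold nonlinearity). Rates are in
    arbitrary units; displays normalize by ``r.max()`` of the post-learning
    run.
    """

    params: RingModelParams
    phis: np.ndarray  # rad, (-pi, pi]
    times: np.ndarray  # ms
    r: np.ndarray
    a: np.ndarray
    x: np.ndarray

    def index_of(self, phi: float) -> int:
        d = np.angle(np.exp(1j * (self.phis - phi)))
        return int(np.argmin(np.abs(d)))


def ring_grid(N: int) -> np.ndarray:
    """N preferred directions uniformly covering (-pi, pi]."""
    return -np.pi + 2 * np.pi * np.arange(1, N + 1) / N


def _wrapped_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * (a - b)))


def _gauss_term(J: float, sigma: float, d: np.ndarray) -> np.ndarray:
    if np.isinf(sigma):
        return np.full_like(d, J)  # sigma = inf: constant profile
    return J * np.exp(-(d**2) / sigma**2)


def build_connectivity(params: RingModelParams, phis: np.ndarray | None = None) -> np.ndarray:
    """Connectivity matrix J[i, j] = J(phi_i - phi_j) on the ring.

    Distances are wrapped to (-pi, pi]; the 2*pi/N integration weight is
    applied where the kernel is used, not here.
    """
    if phis is None:
        phis = ring_grid(params.N)
    d = _wrapped_diff(phis[:, None], phis[None, :])
    return _gauss_term(params.J_E, params.sigma_E, d) - _gauss_term(
        params.J_I, params.sigma_I, d
    )


def spatial_input(params: RingModelParams, phis: np.ndarray | None = None) -> np.ndarray:
    """Feedforward spatial profile: bumps at phi0 and phi0 + pi."""
    if phis is None:
        phis = ring_grid(params.N)
    d0 = _wrapped_diff(phis, params.phi0)
    d1 = _wrapped_diff(phis, params.phi0 + np.pi)
    s2 = params.sigma_stim**2
    return params.gamma0 * (np.exp(-(d0**2) / s2) + params.gamma1 * np.exp(-(d1**2) / s2))


def temporal_input(params: RingModelParams, t: np.ndarray | float) -> np.ndarray | float:
    """Low-pass filtered boxcar: exponential rise during the stimulus and
    exponential decay after it, time constant tau_ext."""
    t = np.asarray(t, float)
    on, off = params.stim_onset, params.stim_onset + params.t_stim
    rise = 1.0 - np.exp(-(t - on) / params.tau_ext)
    peak = 1.0 - np.exp(-params.t_stim / params.tau_ext)
    decay = peak * np.exp(-(t - off) / params.tau_ext)
    out = np.where(t < on, 0.0, np.where(t < off, rise, decay))
    return out if out.ndim else float(out)


def feedforward_input(
    params: RingModelParams, t: float, phis: np.ndarray | None = None
) -> np.ndarray:
    """Separable feedforward current i(phi, t) = i_s(phi) i_t(t)."""
    return spatial_input(params, phis) * temporal_input(params, t)


def simulate(params: RingModelParams) -> RingModelResult:
    """Integrate the rate/adaptation dynamics with fixed-step RK4.

    Starts from r = a = 0, stores r, a and the net input x (the argument of
    the threshold nonlinearity) at every step. Raises if the solution
    diverges (|r| > 1e6), which indicates an unstable dt/parameter choice.
    """
    N, dt = params.N, params.dt
    phis = ring_grid(N)
    Jw = build_connectivity(params, phis) * (2 * np.pi / N)
    i_s = spatial_input(params, phis)
    tau_r, tau_a, k = params.tau_r, params.tau_a, params.k

    n_steps = int(round(params.t_total / dt))
    times = np.arange(n_steps + 1) * dt
    i_t = temporal_input(params, times)
    # RK4 stage times fall between stored samples; evaluate the input exactly
    i_t_half = temporal_input(params, times + dt / 2)

    r = np.zeros(N)
    a = np.zeros(N)
    R = np.empty((N, n_steps + 1))
    A = np.empty((N, n_steps + 1))
    R[:, 0], A[:, 0] = r, a

    def deriv(r, a, drive):
        x = Jw @ r + drive - k * a
        return (np.maximum(x, 0.0) - r) / tau_r, (r - a) / tau_a

    for n in range(n_steps):
        d0, d_half, d1 = i_s * i_t[n], i_s * i_t_half[n], i_s * i_t[n + 1]
        k1r, k1a = deriv(r, a, d0)
        k2r, k2a = deriv(r + dt / 2 * k1r, a + dt / 2 * k1a, d_half)
        k3r, k3a = deriv(r + dt / 2 * k2r, a + dt / 2 * k2a, d_half)
        k4r, k4a = deriv(r + dt * k3r, a + dt * k3a, d1)
        r = r + dt / 6 * (k1r + 2 * k2r + 2 * k3r + k4r)
        a = a + dt / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
        R[:, n + 1], A[:, n + 1] = r, a
        if not np.all(np.abs(r) < 1e6):
            raise FloatingPointError(
                f"rate field diverged at t={times[n + 1]:.1f} ms; "
                f"reduce dt={dt} or check parameters"
            )

    X = Jw @ R + i_s[:, None] * i_t[None, :] - k * A
    return RingModelResult(params=params, phis=phis, times=times, r=R, a=A, x=X)


def dominant_frequency(
    result: RingModelResult,
    phi_probe: float | None = None,
    window: tuple[float, float] | None = None,
    field: str = "r",
    max_resolution_hz: float = 0.25,
) -> float:
    """Spectral peak frequency (Hz) of one population's time course.

    Linear-detrends and Hann-windows the series, zero-pads the FFT to a
    grid of at most ``max_resolution_hz``, and returns the peak of the
    periodogram above 0.5 Hz. Returns nan for a (near-)constant series,
    where a dominant frequency is undefined.
    """
    p = result.params
    if phi_probe is None:
        phi_probe = p.phi0
    if window is None:
        window = (p.stim_onset, p.stim_onset + p.t_stim + 500.0)
    series = getattr(result, field)[result.index_of(phi_probe)]
    mask = (result.times >= window[0]) & (result.times <= window[1])
    y = series[mask]
    if y.size < 16 or np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        return float("nan")
    fs = 1e3 / p.dt  # Hz
    nfft = int(2 ** np.ceil(np.log2(fs / max_resolution_hz)))
    freqs, pxx = signal.periodogram(y, fs=fs, window="hann", detrend="linear", nfft=nfft)
    valid = freqs >= 0.5
    return float(freqs[valid][np.argmax(pxx[valid])])


def model_selectivity(
    result: RingModelResult, window: tuple[float, float] | None = None
) -> dict[str, float]:
    """Time-averaged activity at the stimulated vs opposite direction.

    Returns mean rates at phi0 and phi0+pi over the stimulus window, their
    ratio (nan when the opposite-direction rate is 0) and the mean over all
    populations.
    """
    p = result.params
    if window is None:
        window = (p.stim_onset, p.stim_onset + p.t_stim)
    mask = (result.times >= window[0]) & (result.times <= window[1])
    if not mask.any():
        raise ValueError("selectivity window outside the simulated time range")
    r_pref = float(result.r[result.index_of(p.phi0), mask].mean())
    r_opp = float(result.r[result.index_of(p.phi0 + np.pi), mask].mean())
    return {
        "pref": r_pref,
        "opp": r_opp,
        "ratio": r_pref / r_opp if r_opp > 0 else float("nan"),
        "population_mean": float(result.r[:, mask].mean()),
    }


def net_input_field(result: RingModelResult, norm: float | None = None) -> np.ndarray:
    """Net input x(phi, t) normalized by its maximum (or a supplied one).

    Unlike the rate field, x oscillates at every direction after learning,
    including where r is thresholded to zero.
    """
    if norm is None:
        norm = float(result.x.max())
    if norm == 0:
        raise ValueError("normalization constant is zero")
    return result.x / norm


def cross_spectrum_phase(
    result: RingModelResult,
    phi_a: float,
    phi_b: float,
    freq_hz: float,
    window: tuple[float, float] | None = None,
    field: str = "x",
) -> float:
    """Relative phase (rad) between two populations' series at a frequency.

    Computed from the cross-spectrum of the detrended series; pi means
    anti-phase.
    """
    p = result.params
    if window is None:
        window = (p.stim_onset, p.stim_onset + p.t_stim + 500.0)
    mask = (result.times >= window[0]) & (result.times <= window[1])
    arr = getattr(result, field)
    ya = signal.detrend(arr[result.index_of(phi_a), mask])
    yb = signal.detrend(arr[result.index_of(phi_b), mask])
    fs = 1e3 / p.dt
    nfft = int(2 ** np.ceil(np.log2(fs / 0.25)))
    w = np.hanning(ya.size)
    Fa = np.fft.rfft(ya * w, nfft)
    Fb = np.fft.rfft(yb * w, nfft)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    i = int(np.argmin(np.abs(freqs - freq_hz)))
    return float(np.angle(Fa[i] * np.conj(Fb[i])))


def save_result(result: RingModelResult, path) -> None:
    """Write phis/times/r/a/x (and parameters as attributes) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("phis", "times", "r", "a", "x"):
            f.create_dataset(name, data=getattr(result, name))
        g = f.create_group("params")
        for key, val in vars(result.params).items():
            g.attrs[key] = val


def load_result(path) -> RingModelResult:
    import h5py

    with h5py.File(path, "r") as f:
        params = RingModelParams(**{k: v.item() if hasattr(v, "item") else v for k, v in f["params"].attrs.items()})
        return RingModelResult(
            params=params,
            phis=f["phis"][:],
            times=f["times"][:],
            r=f["r"][:],
            a=f["a"][:],
            x=f["x"][:],
        )
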