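"""Shared fixtures: session-scoped ring-model runs and synthetic recordings.

The ring simulations are the most expensive objects in the suite; they are
simulated once per session and shared by the model and acceptance tests.
"""

import numpy as np
import pytest

from v1osc import ring, synth


@pytest.fixture(scope="session")
def post_result():
    """Post-learning ring simulation at the default discretization."""
    return ring.simulate(ring.post_learning_params())


@pytest.fixture(scope="session")
def pre_result():
    """Pre-learning ring simulation at the default discretization."""
    return ring.simulate(ring.pre_learning_params())


@pytest.fixture(scope="session")
def naive_trials():
    """20 default naive trials with their ground-truth spike trains."""
    return [synth.generate_vm_trial(synth.naive_vm_params(seed=s)) for s in range(20)]


@pytest.fixture(scope="session")
def experienced_trials():
    """20 default experienced trials with ground-truth spike trains."""
    return [
        synth.generate_vm_trial(synth.experienced_vm_params(seed=100 + s)) for s in range(20)
    ]


def cosine_trial(freq=5.0, amp=3.0, fs=1000.0, dur=6.0, stim_onset=0.5, stim_dur=0.5):
    """Pure cosine V_m starting at t=0 (for phase/spectral oracle tests)."""
    from v1osc.traces import VmTrial

    t = np.arange(int(dur * fs)) / fs
    return VmTrial(
        samples=amp * np.cos(2 * np.pi * freq * t),
        sampling_rate=fs,
        stim_onset=stim_onset,
        stim_dur=stim_dur,
    )
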