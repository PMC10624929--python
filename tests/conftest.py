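import numpy as np
import pytest

from intafret.simulate import SimConfig
from intafret.traces import FretTrace


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def quiet_config():
    """Short noiseless-ish config for deterministic structural checks."""
    return SimConfig(
        frame_interval=1.0,
        duration=200.0,
        injection_time=20.0,
        noise_sd=0.0,
        aggregate_rate=0.0,
        seed=7,
    )


def markov_fret_trace(seed, n=1000, level=0.16, sd=0.05, p_on=0.1, p_off=0.2, dt=1.0):
    """Two-state Markov FRET trace with Gaussian noise plus its true path."""
    rng = np.random.default_rng(seed)
    states = np.zeros(n, dtype=int)
    s = 0
    for t in range(1, n):
        if s == 0:
            s = 1 if rng.uniform() < p_on else 0
        else:
            s = 0 if rng.uniform() < p_off else 1
        states[t] = s
    E = np.clip(np.where(states == 1, level, 0.0) + rng.normal(0, sd, n), 0, 1)
    return FretTrace(dt, E, np.zeros(n, dtype=bool)), states
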