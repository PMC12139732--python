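import numpy as np
import pytest

from rapidffr.simulator import SimulationConfig, simulate_recording_pair

F0, FS = 128.0, 16384.0
CYCLE = int(FS / F0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pair():
    """A modest noisy simulated recording pair shared across tests."""
    cfg = SimulationConfig(n_cycles=1000, seed=7)
    return cfg, simulate_recording_pair(cfg)


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free, ramp-free pair for exact-identity checks."""
    cfg = SimulationConfig(n_cycles=400, noise_rms=0.0, ramp_cycles=0, seed=3)
    return cfg, simulate_recording_pair(cfg)
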