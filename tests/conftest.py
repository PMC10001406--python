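import numpy as np
import pytest

from measpike.simulate import SimulationConfig, simulate_device_trains


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def small_truth():
    """One 4-channel, 60 s device with everything active (shared, read-only)."""
    cfg = SimulationConfig(n_channels=4, duration=60.0, p_active=1.0, seed=7)
    return simulate_device_trains(cfg)
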