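import numpy as np
import pytest

from trunkgait import SimulationConfig, simulate_walk


@pytest.fixture(scope="session")
def clean_walk():
    """Noiseless symmetric 20 s walk at 1 stride/s (exactly periodic)."""
    cfg = SimulationConfig(duration_s=20.0, stride_freq_hz=1.0)
    recording, truth = simulate_walk(cfg)
    return cfg, recording, truth


@pytest.fixture(scope="session")
def logistic_series():
    """Fully chaotic logistic map orbit (r = 4), analytic λ = ln 2."""
    rng = np.random.default_rng(12345)
    x = np.empty(3000)
    x[0] = rng.uniform(0.1, 0.9)
    for i in range(1, len(x)):
        x[i] = 4.0 * x[i - 1] * (1.0 - x[i - 1])
    return x


def simulate(seed=0, **kwargs):
    """Shorthand simulator used across tests."""
    cfg = SimulationConfig(rng_seed=seed, **kwargs)
    return simulate_walk(cfg)
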