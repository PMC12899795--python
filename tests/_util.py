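"""Shared helpers for the test suite."""

import numpy as np

from trunkgait import SimulationConfig, TrialConfig, run_trial, simulate_walk


def simulate(seed=0, **kwargs):
    cfg = SimulationConfig(rng_seed=seed, **kwargs)
    return simulate_walk(cfg)


def normalized_axis(recording, axis="vt", n_strides=18):
    """Run preprocessing + events only and return one normalized channel."""
    _, inter = run_trial(
        recording,
        TrialConfig(metrics=frozenset(), n_strides=n_strides),
        return_intermediates=True,
    )
    return inter["normalized"][axis]


def logistic_orbit(n=3000, seed=12345):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.uniform(0.1, 0.9)
    for i in range(1, n):
        x[i] = 4.0 * x[i - 1] * (1.0 - x[i - 1])
    return x
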