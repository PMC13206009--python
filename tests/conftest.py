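import numpy as np
import pytest

from brixband import phantom


@pytest.fixture(scope="session")
def tiny_config():
    """Small 16-band phantom used across unit tests."""
    return phantom.PhantomConfig(
        n_bands=16, height=12, width=12, n_samples=12,
        informative_bands=frozenset({2, 6, 10, 14}), noise_sd=0.01, seed=3)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return phantom.calibrated_dataset(tiny_config)


@pytest.fixture(scope="session")
def recovery_dataset():
    """32-band phantom with 8 planted informative bands."""
    from brixband import experiments

    cfg = experiments.recovery_phantom_config(seed=1)
    x, y = phantom.calibrated_dataset(cfg)
    return cfg, x, y


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        hi, lo = x.copy(), x.copy()
        hi[i] += eps
        lo[i] -= eps
        g[i] = (f(hi) - f(lo)) / (2 * eps)
    return g
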