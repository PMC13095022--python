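import numpy as np
import pytest

from dscanet import nn
from dscanet.data import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def param_rng():
    return nn.seeded_rng(0)


@pytest.fixture(scope="session")
def tiny_samples():
    """Eight deterministic 64×64 synthetic polyp samples."""
    return generate_dataset(SyntheticConfig(image_size=64, seed=11), 8)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central finite differences of a scalar-valued function of ``x``."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g
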