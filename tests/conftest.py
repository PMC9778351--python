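import numpy as np
import pytest

from fuzzyseg import NetworkConfig, PhantomParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Smallest sensible network: 32x32 input, small encoder, all fuzzy blocks."""
    return NetworkConfig(encoder_family="small", input_size=(32, 32), num_classes=5,
                         base_channels=4, seed=11)


@pytest.fixture
def phantom_params():
    return PhantomParams(size=64, seed=0)


@pytest.fixture
def phantom_sample(phantom_params):
    return generate_phantom(phantom_params, seed=5)


def random_memberships(rng, n, c):
    """Vectors uniform on the probability simplex (normalized exponentials)."""
    x = rng.exponential(size=(n, c))
    return x / x.sum(axis=1, keepdims=True)
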