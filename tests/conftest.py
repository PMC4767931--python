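import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_bars():
    """A small flattened bar dataset shared across training sanity tests."""
    from neurovasc.datasets import generate_bar_patterns

    data = generate_bar_patterns(400, 8, 4, np.random.default_rng(77))
    return data.flattened()


@pytest.fixture
def tiny_net():
    """A 4-3-4 autoencoder small enough for finite-difference checks."""
    from neurovasc.autoencoder import Autoencoder

    return Autoencoder(4, 3, learning_rate=0.1, batch_size=2, rng=np.random.default_rng(5))
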