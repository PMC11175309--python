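import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_triple(rng):
    """A generic (A, B, F) triple: two sources and a noisy average."""
    a = rng.random((32, 32))
    b = rng.random((32, 32))
    f = np.clip(0.5 * (a + b) + 0.05 * rng.standard_normal((32, 32)), 0, 1)
    return a, b, f


@pytest.fixture(scope="session")
def small_model():
    """A deterministic desk-scale model, built once per session."""
    from cirf._autodiff import manual_seed
    from cirf.network import FusionModel, ModelConfig

    manual_seed(7)
    model = FusionModel(ModelConfig.small(image_size=64))
    model.eval()
    return model
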