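import numpy as np
import pytest

from sparsemil.data import (
    NegativeBinomialSizes,
    SyntheticSpec,
    generate_synthetic,
)
from sparsemil.model import ModelConfig
from sparsemil.train import TrainConfig, train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(**overrides) -> SyntheticSpec:
    defaults = dict(
        n_bags=60,
        positive_fraction=0.5,
        p=8,
        signal_shift=2.0,
        noise_sd=1.0,
        seed=7,
        bag_size_law=NegativeBinomialSizes(maximum=20),
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def small_bags():
    return generate_synthetic(small_spec())


@pytest.fixture(scope="session")
def small_model_config():
    return ModelConfig(p=8, n_blocks=2)


@pytest.fixture(scope="session")
def quick_train_config():
    return TrainConfig(epochs=60, seed=3)


@pytest.fixture(scope="session")
def trained_small(small_bags, small_model_config, quick_train_config):
    """One trained sparsemax model shared by read-only tests."""
    model, history = train(small_bags, small_model_config, quick_train_config)
    return model, history
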