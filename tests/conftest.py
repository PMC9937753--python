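import numpy as np
import pytest

from ecgan.gan import DiscriminatorConfig, GeneratorConfig
from ecgan.harness import TrainConfig, make_synthetic_dataset
from ecgan.preprocess import NoiseSpec

# Tiny shapes used throughout the unit tests: fragment length 64 keeps the
# five stride-2 blocks (seed length 2) while training in well under a second.
TINY_L = 64

TINY_GEN = GeneratorConfig(fragment_length=TINY_L, seed_length=2,
                           seed_channels=8, block_filters=(8, 8, 8, 8, 8))
TINY_DISC = DiscriminatorConfig(lstm_units=8, conv_filters=4)


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_synthetic_dataset(24, NoiseSpec(("MA", "BW", "EM"), -1.0),
                                  seed=7, fragment_length=TINY_L,
                                  test_fraction=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_train_config(epochs, seed=0, **overrides):
    kwargs = dict(epochs=epochs, learning_rate=1e-3, batch_size=8, seed=seed,
                  eval_subsample=8)
    kwargs.update(overrides)
    return TrainConfig(**kwargs)
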