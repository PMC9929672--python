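import numpy as np
import pytest

from bowtienet import (
    NoiseModel, NetworkSpec, TrainingConfig,
    make_prototypes, sample_dataset, init_network, train,
)


@pytest.fixture(scope="session")
def small_protos():
    return make_prototypes(5, 12, rng_seed=7)


@pytest.fixture(scope="session")
def small_ds(small_protos):
    return sample_dataset(small_protos, NoiseModel(20), n_per_class=120,
                          validation_fraction=1 / 3, rng_seed=8)


@pytest.fixture(scope="session")
def tiny_cfg():
    return TrainingConfig(epochs=60, batch_size=64, rng_seed=9)


@pytest.fixture(scope="session")
def trained_small(small_ds, tiny_cfg):
    """A modestly trained 12-8-5 classifier shared across tests."""
    model = init_network(NetworkSpec(12, 8, 5), rng_seed=10)
    return train(model, small_ds, tiny_cfg)
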