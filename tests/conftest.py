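import numpy as np
import pytest

from mlsbm import (
    BinaryNetwork,
    Hyperparameters,
    MultiLayerNetwork,
    Parcellation,
    SyntheticConfig,
    sample_sbm,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(n, K, M, rng, p=0.4):
    """A small arbitrary multi-layer network with a random partition."""
    layers = []
    for _ in range(M):
        iu = np.triu_indices(n, k=1)
        keep = rng.random(iu[0].size) < p
        layers.append(
            BinaryNetwork(n, zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
        )
    z = Parcellation(rng.integers(0, K, size=n), K)
    return MultiLayerNetwork(layers), z


@pytest.fixture
def small_instance(rng):
    return random_instance(8, 3, 2, rng)


@pytest.fixture
def unit_hypers():
    return Hyperparameters(1.0, 1.0, 1.0)


def planted_instance(n, K, within, between, M, rng):
    from mlsbm import planted_config

    return sample_sbm(planted_config(n, K, within, between, M=M), rng)
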