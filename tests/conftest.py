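import numpy as np
import pytest

from latentdecoder import RegNetConfig, noiseless_config, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> RegNetConfig:
    """A miniature regulatory network (60 genes, 6 regulators) for fast tests."""
    return noiseless_config(n_genes=60, n_regulators=6, connectivity=0.3, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, n_train=40, n_test=20)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
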