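import numpy as np
import pytest

from grainrisk import GeneratorConfig, generate, split


@pytest.fixture(scope="session")
def small_dataset():
    """A small labelled synthetic dataset shared across tests."""
    cfg = GeneratorConfig(seed=7).scaled(600)
    records, labels = generate(cfg)
    return records, labels


@pytest.fixture(scope="session")
def small_split(small_dataset):
    records, labels = small_dataset
    return split(records, labels, train_frac=0.8, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
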