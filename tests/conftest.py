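import numpy as np
import pytest

from granuleco import synthetic


@pytest.fixture(scope="session")
def toy():
    return synthetic.toy_fixture()


@pytest.fixture(scope="session")
def small_tree():
    """40-tip ultrametric Yule tree shared by null-model tests."""
    return synthetic.simulate_tree(40, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)

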