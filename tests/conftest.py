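import numpy as np
import pytest

from tsflow.field import FieldConfig, FieldNet
from tsflow.fixtures import FixtureSpec, make_fixture_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Six small toy reactions spanning three reaction cores."""
    return make_fixture_dataset(
        FixtureSpec(n_reactions=6, seed=3, n_cores=3, n_heavy_range=(3, 4)))


@pytest.fixture(scope="session")
def default_dataset():
    """The full default fixture dataset (200 reactions, 12 cores)."""
    return make_fixture_dataset(FixtureSpec())


@pytest.fixture()
def rxn(tiny_dataset):
    return tiny_dataset[0]


@pytest.fixture()
def tiny_net():
    return FieldNet(FieldConfig(width=16, n_layers=2, n_heads=4, n_rbf=8, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
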