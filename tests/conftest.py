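import numpy as np
import pytest

from mirevol.homology import SpeciesTree
from mirevol.simulate import DEFAULT_TREE, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tree() -> SpeciesTree:
    return SpeciesTree.from_newick(DEFAULT_TREE)


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default (early-bias) configuration."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
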