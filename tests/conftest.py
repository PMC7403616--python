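import numpy as np
import pytest

from gbgcscan import phylo, simulate as sim


@pytest.fixture(scope="session")
def params():
    return sim.default_params()


@pytest.fixture(scope="session")
def core_tree():
    return phylo.index_tree(phylo.read_tree(phylo.CORE_TREE_NEWICK))


@pytest.fixture(scope="session")
def default_tree():
    return phylo.index_tree(phylo.read_tree(phylo.DEFAULT_TREE_NEWICK))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
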