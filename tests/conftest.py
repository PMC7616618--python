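import warnings

import numpy as np
import pytest

from antpath.simulate import simulate_yule
from antpath.treeio import Phylogeny

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="arviz")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_tip_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def five_tip_tree():
    return Phylogeny.from_newick(
        "(((A:0.3,B:0.5):0.4,C:1.0):0.2,(D:0.6,E:0.9):0.5):0;")


@pytest.fixture(scope="session")
def yule100():
    return simulate_yule(100, seed=42)


def random_generator(rng, k=4, sparse=0.0):
    """A random CTMC generator matrix, optionally with zeroed rates."""
    Q = rng.uniform(0.0, 3.0, (k, k))
    if sparse:
        Q[rng.uniform(size=(k, k)) < sparse] = 0.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q
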