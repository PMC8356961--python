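import numpy as np
import pytest

from phylokit import tree_edit
from phylokit.treeio import TreeList

SESSION_SEED = 20240917


@pytest.fixture(scope="session")
def session_seed():
    return SESSION_SEED


def random_trees(n, n_tips, seed, model="yule"):
    return TreeList(
        tree_edit.random_tree(n_tips, model, seed + k) for k in range(n)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(SESSION_SEED)
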