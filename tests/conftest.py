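import numpy as np
import pytest

from nconserve import read_newick, simulate_tree


@pytest.fixture
def three_tip_tree():
    """((A:0.1,B:0.1):0.05,C:0.2); — used for hand-computed distances."""
    return read_newick("((A:0.1,B:0.1):0.05,C:0.2);")


@pytest.fixture
def quartet_tree():
    return read_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")


def random_trees(n_trees, min_tips, max_tips, seed):
    """Deterministic stream of random Yule trees for property tests."""
    rng = np.random.default_rng(seed)
    for i in range(n_trees):
        n = int(rng.integers(min_tips, max_tips + 1))
        yield simulate_tree(n, seed=int(rng.integers(2**31)))
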