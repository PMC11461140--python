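import numpy as np
import pytest

from phyloallom import Phylogeny, read_newick


def make_star_tree(n: int, depth: float = 1.0) -> Phylogeny:
    """Star phylogeny: n tips hanging directly off the root at equal depth."""
    parent = np.r_[np.full(n, n), [-1]].astype(np.int64)
    blen = np.r_[np.full(n, float(depth)), [0.0]]
    return Phylogeny(tuple(f"t{i + 1}" for i in range(n)), parent, blen)


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star20():
    return make_star_tree(20)
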