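import numpy as np
import pandas as pd
import pytest

from corax.phylo import parse_newick
from corax.simulate import SimulationConfig, simulate_dataset, \
    simulate_yule_tree


@pytest.fixture(scope="session")
def tree3():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def star2():
    return parse_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def tree4():
    return parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture(scope="session")
def yule80():
    """A fixed 80-tip pure-birth tree shared across statistical tests."""
    return simulate_yule_tree(80, 0.25, np.random.default_rng(80))


@pytest.fixture(scope="session")
def yule150():
    return simulate_yule_tree(150, 0.25, np.random.default_rng(150))


@pytest.fixture(scope="session")
def dataset():
    """One study-shaped synthetic bundle reused by integration tests."""
    return simulate_dataset(SimulationConfig(seed=11))


def mid_clade(tree, lo, hi):
    """An internal non-root node whose clade size is within [lo, hi]."""
    for v in range(tree.n_nodes):
        if tree.is_tip[v] or v == tree.root:
            continue
        if lo <= len(tree.clade_tips(v)) <= hi:
            return v
    raise RuntimeError("no clade of the requested size")
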