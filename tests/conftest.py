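import numpy as np
import pytest

from treecongruence.synthetic_data import simulate_species_tree
from treecongruence.treeio import parse_newick


@pytest.fixture
def quartet_ab_cd():
    """4-taxon tree with internal split AB|CD of length 0.3, pendants 0.1."""
    return parse_newick("((A:0.1,B:0.1):0.3,C:0.1,D:0.1);")


@pytest.fixture
def quartet_ac_bd():
    """Conflicting 4-taxon tree with internal split AC|BD of length 0.4."""
    return parse_newick("((A:0.1,C:0.1):0.4,B:0.1,D:0.1);")


def random_tree_pair(n_taxa: int, seed: int):
    """Two independent random trees on one taxon set."""
    rng = np.random.default_rng(seed)
    t1 = simulate_species_tree(n_taxa, seed=int(rng.integers(2**31)))
    t2 = simulate_species_tree(n_taxa, seed=int(rng.integers(2**31)), taxa=t1.taxa)
    return t1, t2
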