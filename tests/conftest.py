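import numpy as np
import pytest

from dispersal_pgls.phylo import parse_newick


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); — depths all 2, A/B share 1 unit."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20230208)
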