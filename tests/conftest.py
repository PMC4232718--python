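import numpy as np
import pytest

from cetataste.genetics import GeneticCode
from cetataste.phylo import PhyloTree


@pytest.fixture(scope="session")
def code():
    return GeneticCode.standard()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_tree():
    return PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.15,D:0.3);")


@pytest.fixture()
def five_taxon_tree():
    return PhyloTree.from_newick(
        "(((A:0.15,B:0.15):0.08,C:0.2):0.05,(D:0.2,E:0.2):0.05);"
    )
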