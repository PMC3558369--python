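import pytest

from osmkit.groups import k3st, z4_dna
from osmkit.phylo import parse_newick

FIG1 = "((1,2));"
FIG2 = "((1,2),(3,(4,5)));"


@pytest.fixture(scope="session")
def K3ST():
    return k3st()


@pytest.fixture(scope="session")
def Z4():
    """Cyclic nucleotide group generated by A→G→T→C→A."""
    return z4_dna()


@pytest.fixture()
def fig1_tree():
    """Rooted two-taxon cherry with a stem edge."""
    return parse_newick(FIG1)


@pytest.fixture()
def fig2_tree():
    """The five-taxon tree ((1,2),(3,(4,5))) used in the worked examples."""
    return parse_newick(FIG2)
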