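import numpy as np
import pytest

from c4recruit.seq_core import PhyloTree, read_newick_string


@pytest.fixture(scope="session")
def eight_taxon_tree() -> PhyloTree:
    """Small tree with Flaveria-scale branch lengths for codon-model tests."""
    return read_newick_string(
        "((a:0.08,b:0.08)i1:0.05,((c:0.06,d:0.06)i2:0.04,"
        "((e:0.05,f:0.05)i3:0.03,(g:0.05,h:0.05)i4:0.03)i5:0.03)i6:0.04)r;")


@pytest.fixture(scope="session")
def six_tip_tree() -> PhyloTree:
    return read_newick_string(
        "((A:1,B:1)n1:1,((C:1,D:1)n2:1,(E:1,F:1)n3:1)n4:1)root;")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
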