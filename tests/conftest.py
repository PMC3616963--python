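import numpy as np
import pytest

from cohesim import seqsim
from cohesim.seqsim import SimParams, default_species_tree


@pytest.fixture(scope="session")
def species():
    return default_species_tree()


@pytest.fixture(scope="session")
def clonal_gene(species):
    """One deterministic clonal 1 kb gene."""
    return seqsim.simulate_gene(species, SimParams(seq_length=1002, seed=42))


@pytest.fixture(scope="session")
def clonal_seqs(clonal_gene):
    return clonal_gene.sequences()


@pytest.fixture(scope="session")
def mosaic_seqs(species):
    """Two halves evolved on trees with conflicting within-clade
    resolutions and exaggerated stems: an unambiguous recombinant."""
    from cohesim.trees import parse_newick

    n1 = ("((wRi:0.05,wHa:0.05):0.12,wMel:0.1,"
          "((wPip:0.05,wAlbB:0.05):0.12,wNo:0.1):0.35);")
    n2 = ("((wRi:0.05,wMel:0.05):0.12,wHa:0.1,"
          "((wPip:0.05,wNo:0.05):0.12,wAlbB:0.1):0.35);")
    a = seqsim.simulate_gene_on_tree(parse_newick(n1), species,
                                     SimParams(seq_length=501, seed=1))
    b = seqsim.simulate_gene_on_tree(parse_newick(n2), species,
                                     SimParams(seq_length=501, seed=2))
    return {lab: a.sequences()[lab] + b.sequences()[lab] for lab in a.labels}
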