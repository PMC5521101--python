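import numpy as np
import pytest

from psgscan._phylo import IndexedTree
from psgscan.io_formats import CodonAlignment
from psgscan.synthetic_data import SimulationConfig, simulate_codon_alignment


@pytest.fixture(scope="session")
def three_taxon_tree() -> IndexedTree:
    return IndexedTree.from_newick("((A:0.2,B:0.35):0.15,C:0.4);")


@pytest.fixture(scope="session")
def nine_taxon_m8():
    """One seeded M8 alignment (300 codons, 9 taxa) with its true site
    classes and tree; session-scoped because fits on it are reused."""
    config = SimulationConfig(seed=7, model="M8", p0=0.9, omega_s=3.0,
                              beta_p=0.5, beta_q=1.5, kappa=2.0,
                              n_codons=300, tree_length=3.0)
    aln, site_class, tree = simulate_codon_alignment(config)
    return config, aln, site_class, tree


@pytest.fixture(scope="session")
def m8_sites_fit(nine_taxon_m8):
    from psgscan.selection_inference import sites_test
    _, aln, _, tree = nine_taxon_m8
    return sites_test(aln, tree, n_starts=1, seed=0)


def toy_alignment(seqs: dict[str, str], gene_id: str = "toy"
                  ) -> CodonAlignment:
    return CodonAlignment(gene_id, list(seqs), list(seqs.values()))
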