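import pytest
from hypothesis import settings

from mitospectrum.mito_model import CircularGenome, GeneAnnotation

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from mitospectrum.synthetic_data import (SpectrumParams, simulate_genome,
                                         simulate_tree_and_mutations)


@pytest.fixture(scope="session")
def sim_genome():
    """Session-wide default synthetic genome (~13.7 kb, 12 protein genes)."""
    return simulate_genome(seed=11)


@pytest.fixture(scope="session")
def sim_run(sim_genome):
    """A clean low-rate simulation: (tree, ledger, leaf sequences)."""
    params = SpectrumParams(mutations_per_branch=2.0,
                            heteroplasmic_fraction=0.0)
    return simulate_tree_and_mutations(sim_genome, 12, params, seed=5)


@pytest.fixture
def toy_genome():
    """Tiny hand-built genome: one 4-codon gene flanked by noncoding runs.

    Layout (1-based): 1-6 noncoding, 7-18 geneA = ATG GCT CTA TTT,
    19-24 noncoding.
    """
    seq = "AATTCC" + "ATGGCTCTATTT" + "GGCCAA"
    ann = [GeneAnnotation("geneA", 7, 18, "+", "protein", "I")]
    return CircularGenome(sequence=seq, annotations=ann)
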