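"""Genetic-code, site-classification and variant-annotation checks.

The degeneracy oracle is a hand-typed invertebrate-mitochondrial codon
table, independent of the package's table source.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitospectrum import genetic_code as gc
from mitospectrum.mito_model import (CircularGenome, GeneAnnotation,
                                     OverlapError, annotate_variant,
                                     classify_site, count_syn_nonsyn_sites)

# Hand-typed invertebrate mitochondrial code (differs from the standard
# code at ATA=Met, TGA=Trp, AGA/AGG=Ser).
TABLE5 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "M", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "S", "AGG": "S",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

ALL_CODONS = sorted(TABLE5)
SENSE_CODONS = [c for c in ALL_CODONS if TABLE5[c] != "*"]


def oracle_degeneracy(codon, pos):
    """Degeneracy by exhaustive enumeration against the hand-typed table."""
    aa = TABLE5[codon]
    n_syn = sum(
        1 for b in "ACGT" if b != codon[pos]
        and TABLE5[codon[:pos] + b + codon[pos + 1:]] == aa)
    return {3: "four", 0: "non"}.get(n_syn, "two")


def test_codon_table_matches_hand_typed_oracle():
    assert gc.codon_table(5) == TABLE5


@pytest.mark.parametrize("pos", [0, 1, 2])
def test_degeneracy_matches_enumeration_oracle(pos):
    for codon in SENSE_CODONS:
        assert gc.degeneracy_class(codon, pos) == oracle_degeneracy(codon, pos), \
            (codon, pos)


def test_second_codon_position_always_nondegenerate():
    for codon in SENSE_CODONS:
        assert gc.degeneracy_class(codon, 1) == "non"


def test_known_third_position_degeneracies():
    assert gc.degeneracy_class("CTA", 2) == "four"   # Leu box
    assert gc.degeneracy_class("TTT", 2) == "two"    # Phe
    assert gc.degeneracy_class("ATG", 2) == "two"    # Met (ATA=Met)


def test_codon_family_partition():
    fams = gc.codon_families(5)
    by_class = {}
    for v in fams.values():
        by_class.setdefault(v["degeneracy"], []).append(v)
    assert len(by_class["two"]) == 13
    assert len(by_class["four"]) == 9   # six-fold Leu/Ser split by box
    # every sense codon in exactly one family of size >= 2, plus the
    # single-codon families that do not exist under this code
    members = [c for v in fams.values() for c in v["codons"]]
    assert len(members) == len(set(members))


def test_classify_site_gene_and_noncoding(toy_genome):
    # geneA = ATG GCT CTA TTT at 7..18
    sc = classify_site(toy_genome, 15)     # third position of CTA
    assert (sc.gene, sc.codon_position, sc.degeneracy) == ("geneA", 3, "four")
    sc = classify_site(toy_genome, 18)     # third position of TTT
    assert sc.degeneracy == "two"
    sc = classify_site(toy_genome, 9)      # third position of ATG
    assert sc.degeneracy == "two"
    sc = classify_site(toy_genome, 8)      # second position
    assert sc.degeneracy == "non"
    sc = classify_site(toy_genome, 3)
    assert sc.feature_type == "noncoding" and sc.codon_position is None
    with pytest.raises(IndexError):
        classify_site(toy_genome, 0)
    with pytest.raises(IndexError):
        classify_site(toy_genome, len(toy_genome) + 1)


def test_overlapping_protein_genes_rejected():
    with pytest.raises(OverlapError):
        CircularGenome("ATGGCTCTATTTGGCCAA", [
            GeneAnnotation("a", 1, 12, "+", "protein"),
            GeneAnnotation("b", 10, 18, "+", "protein")])


def test_minus_strand_codon_logic():
    # gene on minus strand: genome 5'->3' is the reverse complement of the
    # CDS; CDS = ATG GCT CTA TTT
    cds = "ATGGCTCTATTT"
    rc = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    g = CircularGenome("AATTCC" + rc + "GGCCAA",
                       [GeneAnnotation("geneR", 7, 18, "-", "protein")])
    assert g.cds(g.annotations[0]) == cds
    # genome position 7 is the CDS's last base (third position of TTT)
    sc = classify_site(g, 7)
    assert (sc.codon_position, sc.degeneracy) == (3, "two")


# -- variant annotation -------------------------------------------------------

def test_annotate_synonymous_at_fourfold(toy_genome):
    v = annotate_variant(toy_genome, 15, "A", "G")   # CTA -> CTG, Leu
    assert v.effect == "synonymous" and v.kind == "SNP"


def test_annotate_nonsynonymous(toy_genome):
    v = annotate_variant(toy_genome, 11, "C", "A")   # GCT -> GAT, Ala->Asp
    assert v.effect == "nonsynonymous"


def test_annotate_frameshift_insertion(toy_genome):
    v = annotate_variant(toy_genome, 11, "C", "CA")
    assert v.kind == "insertion" and v.effect == "frameshift"


def test_annotate_inframe_deletion(toy_genome):
    anc = "".join(toy_genome.base(p) for p in range(10, 14))
    v = annotate_variant(toy_genome, 10, anc, anc[0])
    assert v.kind == "deletion" and v.effect == "in-frame-indel"


def test_annotate_noncoding_indel(toy_genome):
    anc = "".join(toy_genome.base(p) for p in (2, 3))
    v = annotate_variant(toy_genome, 2, anc, anc[0])
    assert v.effect == "noncoding"


def test_annotate_rejects_wrong_ancestral_context(toy_genome):
    wrong = "G" if toy_genome.base(15) != "G" else "C"
    with pytest.raises(ValueError, match="disagrees"):
        annotate_variant(toy_genome, 15, wrong, "T")


def test_paired_indels_each_annotated_frameshift(toy_genome):
    # a 1-bp deletion and nearby 1-bp insertion are frameshifts one by one
    # even though jointly frame-preserving
    del_anc = "".join(toy_genome.base(p) for p in (10, 11))
    v1 = annotate_variant(toy_genome, 10, del_anc, del_anc[0])
    v2 = annotate_variant(toy_genome, 16, toy_genome.base(16),
                          toy_genome.base(16) + "T")
    assert v1.effect == v2.effect == "frameshift"


# -- site counting ------------------------------------------------------------

def test_site_count_examples():
    S, N = count_syn_nonsyn_sites("GCT")
    assert S == pytest.approx(1.0) and N == pytest.approx(2.0)
    S, N = count_syn_nonsyn_sites("ATG")   # only ATG->ATA synonymous
    assert S == pytest.approx(1 / 3)


def test_site_count_rejects_internal_stop():
    with pytest.raises(ValueError, match="stop"):
        count_syn_nonsyn_sites("ATGTAAGCT")


@settings(max_examples=50, deadline=None)
@given(st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=40))
def test_site_count_conserves_length(codons):
    cds = "".join(codons)
    S, N = count_syn_nonsyn_sites(cds)
    assert S + N == pytest.approx(len(cds))


def test_truncated_final_codon_excluded():
    S, N = count_syn_nonsyn_sites("GCTTT")   # trailing TT dropped
    assert S + N == pytest.approx(3.0)
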