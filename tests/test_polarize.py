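"""Clustering, Fitch reconstruction vs brute force, cataloging, collapsing."""

import dendropy
import numpy as np
import pytest

from mitospectrum.polarize import (catalog_mutations, cluster_mitotypes,
                                   collapse_duplicate_lineages,
                                   flag_contamination, ledger_recovery,
                                   reconstruct_ancestors)
from mitospectrum.synthetic_data import SpectrumParams, simulate_tree_and_mutations


# -- brute-force parsimony oracle ---------------------------------------------

def brute_force_parsimony(tree, leaf_seqs, alphabet="ACGT"):
    """Minimum change count over all internal-node labelings, per site."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    L = len(next(iter(leaf_seqs.values())))
    k = len(internal)
    idx = {n: i for i, n in enumerate(internal)}
    A = len(alphabet)
    code = {c: i for i, c in enumerate(alphabet)}

    # all A^k internal labelings as an integer matrix (A^k, k)
    n_lab = A ** k
    labelings = np.zeros((n_lab, k), dtype=np.int8)
    for j in range(k):
        labelings[:, j] = (np.arange(n_lab) // (A ** j)) % A

    total = 0
    leaf_state = {n: np.array([code[c] for c in leaf_seqs[n.label]])
                  for n in leaves}
    for site in range(L):
        changes = np.zeros(n_lab, dtype=np.int32)
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            p = labelings[:, idx[node.parent_node]]
            c = (leaf_state[node][site] if node.is_leaf()
                 else labelings[:, idx[node]])
            changes += (p != c)
        total += int(changes.min())
    return total


def random_instance(rng, n_taxa, n_sites):
    taxa = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tips = [tree.seed_node]
    while len(tips) < n_taxa:
        pick = tips[int(rng.integers(len(tips)))]
        a, b = dendropy.Node(), dendropy.Node()
        pick.add_child(a)
        pick.add_child(b)
        tips.remove(pick)
        tips.extend([a, b])
    for name, tip in zip(taxa, tips):
        tip.taxon = tns.new_taxon(name)
    seqs = {t: "".join(rng.choice(list("ACGT"), size=n_sites)) for t in taxa}
    return tree, seqs, taxa[0]


def test_fitch_score_equals_brute_force_minimum():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n_taxa = int(rng.integers(5, 9))
        tree, seqs, outgroup = random_instance(rng, n_taxa, 12)
        phylo = reconstruct_ancestors(tree, seqs, outgroup)
        assert phylo.parsimony_score == brute_force_parsimony(tree, seqs)
        # cataloged SNP records realize exactly that many changes
        assert len(catalog_mutations(phylo, merge_adjacent_gaps=False)) == \
            phylo.parsimony_score


def test_identical_leaves_reconstruct_with_zero_changes():
    tree, seqs, outgroup = random_instance(np.random.default_rng(1), 6, 30)
    seqs = {k: "ACGTACGT" for k in seqs}
    phylo = reconstruct_ancestors(tree, seqs, outgroup)
    assert phylo.parsimony_score == 0
    assert set(phylo.states.values()) == {"ACGTACGT"}


def test_cherry_polarized_toward_outgroup():
    tree = dendropy.Tree.get(data="((a,b),out);", schema="newick")
    phylo = reconstruct_ancestors(tree, {"a": "A", "b": "G", "out": "A"}, "out")
    ms = catalog_mutations(phylo)
    assert phylo.parsimony_score == 1
    recs = [(m.branch_id, m.ancestral, m.derived) for m in ms.mutations]
    assert recs == [("b", "A", "G")]


def test_clade_shared_variant_emitted_once_on_stem():
    tree = dendropy.Tree.get(data="(((a,b),c),out);", schema="newick")
    seqs = {"a": "G", "b": "G", "c": "A", "out": "A"}
    phylo = reconstruct_ancestors(tree, seqs, "out")
    ms = catalog_mutations(phylo)
    assert len(ms) == 1
    m = ms.mutations[0]
    assert m.origin == "ancestral_branch" and (m.ancestral, m.derived) == ("A", "G")


def test_non_binary_tree_rejected():
    tree = dendropy.Tree.get(data="(a,b,c);", schema="newick")
    with pytest.raises(ValueError, match="non-binary"):
        reconstruct_ancestors(tree, {"a": "A", "b": "A", "c": "A"}, "a")


def test_adjacent_gap_columns_merge_into_one_indel():
    tree = dendropy.Tree.get(data="((a,b),out);", schema="newick")
    seqs = {"a": "A--T", "b": "ACGT", "out": "ACGT"}
    phylo = reconstruct_ancestors(tree, seqs, "out")
    ms = catalog_mutations(phylo)
    assert len(ms) == 1
    m = ms.mutations[0]
    assert (m.position, m.ancestral, m.derived) == (2, "CG", "--")


def test_simulated_ledger_recovery(sim_genome, sim_run):
    tree, ledger, leaves = sim_run
    phylo = reconstruct_ancestors(tree, leaves, "outgroup")
    ms = catalog_mutations(phylo)
    stem = next(c.label for c in tree.seed_node.child_nodes()
                if c.label != "outgroup")
    got, total = ledger_recovery(ledger.consensus_entries(), ms,
                                 exclude_branches=("outgroup", stem))
    assert total > 20
    assert got == total


# -- clustering ---------------------------------------------------------------

def test_cluster_mitotypes_partitions():
    seqs = {"i1": "AAA", "i2": "AAA", "i3": "AAT", "i4": "AAC", "i5": "AAT"}
    reps, member_of = cluster_mitotypes(seqs)
    assert len(reps) == 3
    assert sorted(reps["i1"]) == ["i1", "i2"]
    assert member_of["i5"] == "i3"
    assert len(cluster_mitotypes({"a": "X" * 3})[0]) == 1


def test_cluster_rejects_empty_and_ragged():
    with pytest.raises(ValueError):
        cluster_mitotypes({})
    with pytest.raises(ValueError):
        cluster_mitotypes({"a": "AA", "b": "AAA"})


# -- duplicate collapsing -------------------------------------------------------

def test_collapse_duplicates_keeps_largest_set():
    sets = {"x": [("p1", "A", "G"), ("p2", "C", "T")],
            "y": [("p1", "A", "G"), ("p2", "C", "T"), ("p3", "A", "T")],
            "z": [("p9", "G", "A")]}
    retained = collapse_duplicate_lineages(sets)
    assert retained == ["y", "z"]


def test_collapse_identical_sets_keeps_one():
    sets = {"b": [("p1",)], "a": [("p1",)]}
    assert collapse_duplicate_lineages(sets) == ["a"]


def test_collapse_disjoint_sets_keeps_all():
    sets = {"a": [("p1",)], "b": [("p2",)]}
    assert collapse_duplicate_lineages(sets) == ["a", "b"]


# -- contamination --------------------------------------------------------------

def test_contamination_flagging_rule():
    het = {"iso1": [(("p", i), 0.20 + 0.002 * i) for i in range(5)],
           "iso2": [(("p", 0), 0.40)]}
    homo = {"mito9": {("p", i) for i in range(5)}}
    flagged = flag_contamination(het, homo)
    assert "iso1" in flagged and "iso2" not in flagged
    assert flagged["iso1"] == pytest.approx(0.204, abs=0.01)


def test_contamination_requires_tight_frequencies():
    het = {"iso1": [(("p", 0), 0.10), (("p", 1), 0.50), (("p", 2), 0.90)]}
    homo = {"m": {("p", 0), ("p", 1), ("p", 2)}}
    assert flag_contamination(het, homo) == {}


def test_synthetic_two_mitotype_mixture_flagged():
    rng = np.random.default_rng(8)
    variants = [("v", i) for i in range(6)]
    freqs = 0.20 + rng.normal(0, 0.01, size=6)
    het = {"mix": list(zip(variants, freqs))}
    homo = {"donor": set(variants)}
    flagged = flag_contamination(het, homo)
    assert flagged["mix"] == pytest.approx(0.20, abs=0.03)
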