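"""Codon families, composition-adjusted RSCU, MC tests and preferred flux."""

import math

import numpy as np
import pytest

from mitospectrum.codon_usage import (CodonFamily, classify_preferred_flux,
                                      family_composition, family_vs_rest_test,
                                      preferred_codons, preferred_flux_test,
                                      rscu_adjusted,
                                      third_position_background)
from mitospectrum.datasets import PREFERRED_FLUX_2X2


def make_family(counts, degeneracy="four", box="GC", aa="A"):
    codons = tuple(box + b for b in "ACGT")[:len(counts)]
    return CodonFamily(name=f"{aa}-{box}N", amino_acid=aa, box=box,
                       codons=codons, degeneracy=degeneracy,
                       counts=dict(zip(codons, counts)))


def test_family_composition_of_repeated_codon():
    fams = family_composition({"g": "GCT" * 10})
    ala = next(f for f in fams if f.name.startswith("A-GC"))
    assert ala.counts == {"GCA": 0, "GCC": 0, "GCG": 0, "GCT": 10}
    assert sum(f.total for f in fams) == 10


def test_family_composition_rejects_internal_stop():
    with pytest.raises(ValueError, match="geneX"):
        family_composition({"geneX": "GCTTAAGCT"})


def test_family_counts_conserve_amino_acid_usage(sim_genome):
    cds_set = {g.name: sim_genome.cds(g) for g in sim_genome.protein_genes()}
    fams = family_composition(cds_set, sim_genome.code_id)
    n_codons = sum(len(c) // 3 for c in cds_set.values())
    in_families = sum(f.total for f in fams)
    # codons in 2+-codon families; the remainder belongs to single-codon
    # families (none under this code) — so everything is covered
    assert in_families == n_codons


def test_rscu_one_when_usage_matches_background():
    fam = make_family([10, 20, 30, 40])
    bkg = {"four": {"A": 0.1, "C": 0.2, "G": 0.3, "T": 0.4}}
    values = rscu_adjusted([fam], bkg)
    assert all(v == pytest.approx(1.0) for v in values.values())


def test_rscu_exclusive_codon_under_uniform_background():
    fam = make_family([40, 0, 0, 0])
    bkg = {"four": {b: 0.25 for b in "ACGT"}}
    values = rscu_adjusted([fam], bkg)
    assert values["GCA"] == pytest.approx(4.0)
    assert values["GCC"] == values["GCG"] == values["GCT"] == 0.0


def test_rscu_matches_hand_computed_expectation():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 100, size=4)
    bkg_v = rng.dirichlet(np.ones(4))
    fam = make_family(list(counts))
    bkg = {"four": dict(zip("ACGT", bkg_v))}
    values = rscu_adjusted([fam], bkg)
    total = counts.sum()
    for i, codon in enumerate(fam.codons):
        w = bkg[ "four"][codon[2]]
        wsum = sum(bkg["four"][c[2]] for c in fam.codons)
        assert values[codon] == pytest.approx(
            counts[i] / (total * w / wsum), abs=1e-12)


def test_rscu_expected_counts_sum_to_observed():
    fam = make_family([7, 13, 2, 28])
    values = rscu_adjusted([fam])
    bkg = third_position_background([fam], "four")
    wsum = sum(bkg[c[2]] for c in fam.codons)
    expected_total = sum(fam.total * bkg[c[2]] / wsum for c in fam.codons)
    assert expected_total == pytest.approx(fam.total)


def test_unused_family_gives_nan():
    fam = make_family([0, 0, 0, 0])
    bkg = {"four": {b: 0.25 for b in "ACGT"}}
    assert all(math.isnan(v) for v in rscu_adjusted([fam], bkg).values())


# -- Monte-Carlo family test ----------------------------------------------------

def test_family_identical_to_remainder_is_null():
    fam = make_family([100, 200, 300, 400])
    rest = make_family([1000, 2000, 3000, 4000], box="GT", aa="V")
    chi2, p, sig = family_vs_rest_test(fam, [rest], n_sim=2000, seed=1)
    assert p > 0.5 and not sig


def test_degenerate_single_category_family_warns_not_crashes():
    fam = make_family([5], degeneracy="two", box="TG", aa="W")
    fam.counts = {"TGA": 5}
    fam2 = CodonFamily(name="W2", amino_acid="W", box="TG",
                       codons=("TGA",), degeneracy="two", counts={"TGA": 3})
    chi2, p, sig = family_vs_rest_test(fam, [fam2], n_sim=1000, seed=1)
    assert p == 1.0 and not sig


def test_mc_p_within_binomial_noise_of_asymptotic():
    from scipy import stats
    fam = make_family([260, 240, 255, 245])
    rest = make_family([2500, 2400, 2550, 2550], box="GT", aa="V")
    n_sim = 4000
    chi2, p_mc, _ = family_vs_rest_test(fam, [rest], n_sim=n_sim, seed=7)
    obs = np.array([[fam.counts[c] for c in fam.codons],
                    [rest.counts[c] for c in rest.codons]])
    p_asym = stats.chi2_contingency(obs, correction=False)[1]
    sigma = math.sqrt(p_asym * (1 - p_asym) / n_sim)
    assert abs(p_mc - p_asym) < 3 * sigma + 1 / n_sim


# -- preferred codons -----------------------------------------------------------

def test_preferred_map_idempotent_and_member(sim_genome):
    cds_set = {g.name: sim_genome.cds(g) for g in sim_genome.protein_genes()}
    fams = family_composition(cds_set, sim_genome.code_id)
    pref1 = preferred_codons(fams)
    pref2 = preferred_codons(family_composition(cds_set, sim_genome.code_id))
    assert pref1 == pref2
    by_name = {f.name: f for f in fams}
    for name, codon in pref1.items():
        assert codon in by_name[name].codons


def test_preferred_tie_breaks_lexicographically():
    fam = make_family([5, 5, 0, 0])
    assert preferred_codons([fam]) == {"A-GCN": "GCA"}


def test_flux_test_reproduces_published_g_statistic():
    flux = {"rare": {"from": PREFERRED_FLUX_2X2[0][0],
                     "to": PREFERRED_FLUX_2X2[0][1]},
            "shared": {"from": PREFERRED_FLUX_2X2[1][0],
                       "to": PREFERRED_FLUX_2X2[1][1]}}
    G, dof, p = preferred_flux_test(flux)
    assert round(G, 2) == 6.56 and dof == 1


def test_flux_test_zero_when_classes_identical():
    flux = {"rare": {"from": 30, "to": 20}, "shared": {"from": 30, "to": 20}}
    G, dof, p = preferred_flux_test(flux)
    assert G == pytest.approx(0.0)


def test_classify_preferred_flux_requires_map(sim_genome):
    with pytest.raises(ValueError, match="empty"):
        classify_preferred_flux([], sim_genome, {})


def test_classify_preferred_flux_directions(sim_genome):
    from mitospectrum.mito_model import annotate_variant, classify_site
    cds_set = {g.name: sim_genome.cds(g) for g in sim_genome.protein_genes()}
    fams = family_composition(cds_set, sim_genome.code_id)
    pref = preferred_codons(fams)
    pref_set = set(pref.values())
    # find a four-fold site whose codon is preferred and mutate away
    L = len(sim_genome)
    for gene in sim_genome.protein_genes():
        done = False
        for p in gene.positions(L):
            sc = classify_site(sim_genome, p)
            if sc.degeneracy != "four":
                continue
            _, codon, cp, _ = sim_genome.codon_at(p)
            if codon in pref_set and cp == 3:
                other = next(b for b in "ACGT"
                             if b != codon[2]
                             and codon[:2] + b not in pref_set)
                v = annotate_variant(sim_genome, p, codon[2], other,
                                     origin="terminal_branch")
                flux = classify_preferred_flux([v], sim_genome, pref)
                assert flux["rare"]["from"] == 1
                done = True
                break
        if done:
            break
    assert done
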