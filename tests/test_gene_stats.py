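"""G-tests, Fisher N/S tests and per-gene/per-complex rate tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mitospectrum.datasets import PREFERRED_FLUX_2X2
from mitospectrum.gene_stats import (complex_table, g_test, g_test_2x2,
                                     per_gene_table)
from mitospectrum.mito_model import annotate_variant
from mitospectrum.synthetic_data import (SpectrumParams, simulate_genome,
                                         simulate_tree_and_mutations)


def test_g_zero_when_observed_equals_expected():
    G, dof, p = g_test([10, 20, 30], [10, 20, 30])
    assert G == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_g_test_2x2_reproduces_preferred_flux_statistic():
    G, dof, p = g_test_2x2(PREFERRED_FLUX_2X2)
    assert round(G, 2) == 6.56
    assert dof == 1
    assert p == pytest.approx(0.0104, abs=5e-4)


def g_oracle(obs, exp):
    return 2 * sum(o * np.log(o / e) for o, e in zip(obs, exp) if o > 0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(1, 400), min_size=2, max_size=6))
def test_g_test_matches_direct_formula(obs):
    exp = [sum(obs) / len(obs)] * len(obs)
    G, dof, p = g_test(obs, exp)
    assert G == pytest.approx(g_oracle(obs, exp), abs=1e-9)
    assert dof == len(obs) - 1


def test_g_test_rejects_bad_input():
    with pytest.raises(ValueError):
        g_test([-1, 2], [1, 2])
    with pytest.raises(ValueError):
        g_test([1, 2], [0, 3])


@settings(max_examples=30, deadline=None)
@given(st.integers(500, 2000), st.integers(500, 2000),
       st.floats(0.5, 2.0), st.floats(-0.02, 0.02))
def test_g_and_pearson_agree_on_large_near_null_tables(a, b, scale, eps):
    # asymptotic equivalence of G and Pearson chi-square holds for large
    # tables close to independence
    table = [[a, b], [int(a * scale), max(1, int(b * scale * (1 + eps)))]]
    G, _, _ = g_test_2x2(table)
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    if chi2 > 1:
        assert abs(G - chi2) / chi2 < 0.01


# -- per-gene tables --------------------------------------------------------

def _variants(genome, ledger):
    out = []
    for e in ledger.snps():
        if genome.base(e.position) != e.ancestral:
            continue
        out.append(annotate_variant(genome, e.position, e.ancestral,
                                    e.derived, origin=e.origin))
    return out


@pytest.fixture(scope="module")
def gene_table_inputs():
    genome = simulate_genome(seed=21)
    params = SpectrumParams(mutations_per_branch=30.0,
                            heteroplasmic_fraction=0.0)
    _, ledger, _ = simulate_tree_and_mutations(genome, 16, params, seed=22)
    return genome, _variants(genome, ledger)


def test_per_gene_counts_conserved(gene_table_inputs):
    genome, variants = gene_table_inputs
    rows = per_gene_table(variants, genome)
    coding = [v for v in variants
              if v.effect in ("synonymous", "nonsynonymous")]
    assert sum(r.syn_count for r in rows) == \
        sum(1 for v in coding if v.effect == "synonymous")
    assert sum(r.nonsyn_count for r in rows) == \
        sum(1 for v in coding if v.effect == "nonsynonymous")
    assert len(rows) == 12
    assert all(r.bonferroni_alpha == pytest.approx(0.05 / 12) for r in rows)


def test_uniform_simulation_rarely_significant(gene_table_inputs):
    # no gene effect was planted: at most a false positive or two should
    # pass the Bonferroni threshold
    genome, variants = gene_table_inputs
    rows = per_gene_table(variants, genome)
    n_sig = sum(r.significant("total") for r in rows)
    assert n_sig <= 1


def test_all_variants_in_one_gene_is_extreme():
    genome = simulate_genome(n_genes=2, gene_lengths=[300, 300], seed=5,
                             n_trna=2, rrna_lengths=(60,),
                             control_region_length=30)
    gene = genome.protein_genes()[0]
    variants = []
    for p in list(gene.positions(len(genome)))[:40]:
        anc = genome.base(p)
        der = "A" if anc != "A" else "G"
        variants.append(annotate_variant(genome, p, anc, der))
    rows = per_gene_table(variants, genome)
    row = next(r for r in rows if r.name == gene.name)
    assert row.p_total < 1e-3


def test_complex_counts_equal_sum_of_member_genes(gene_table_inputs):
    genome, variants = gene_table_inputs
    gene_rows = {r.name: r for r in per_gene_table(variants, genome)}
    complex_rows = complex_table(variants, genome)
    assert {r.name for r in complex_rows} == {"I", "III", "IV", "V"}
    assert all(r.bonferroni_alpha == pytest.approx(0.05 / 4)
               for r in complex_rows)
    by_complex = {}
    for g in genome.protein_genes():
        by_complex.setdefault(g.complex_, []).append(g.name)
    for row in complex_rows:
        assert row.syn_count == sum(gene_rows[n].syn_count
                                    for n in by_complex[row.name])
        assert row.nonsyn_count == sum(gene_rows[n].nonsyn_count
                                       for n in by_complex[row.name])


def test_single_complex_genome_rejected():
    genome = simulate_genome(n_genes=2, gene_lengths=[300, 300], seed=5,
                             n_trna=2, rrna_lengths=(60,),
                             control_region_length=30)
    # default complexes for the first two genes are I and V; force one
    from dataclasses import replace
    genome.annotations = [
        replace(a, complex_="I") if a.feature_type == "protein" else a
        for a in genome.annotations]
    with pytest.raises(ValueError, match="two complexes"):
        complex_table([], genome)


def test_planted_nonsynonymous_excess_in_complex_I():
    genome = simulate_genome(seed=31)
    params = SpectrumParams(mutations_per_branch=25.0,
                            heteroplasmic_fraction=0.0)
    _, ledger, _ = simulate_tree_and_mutations(genome, 16, params, seed=32)
    variants = _variants(genome, ledger)
    # plant the effect: double the nonsynonymous count in complex-I genes
    # by duplicating those records
    complex_I = {g.name for g in genome.protein_genes() if g.complex_ == "I"}
    extra = [v for v in variants
             if v.effect == "nonsynonymous" and v.site_class.gene in complex_I]
    rows = complex_table(variants + extra, genome)
    row_I = next(r for r in rows if r.name == "I")
    others = [r for r in rows if r.name != "I"]
    assert row_I.ns_ratio > max(r.ns_ratio for r in others)
    assert row_I.p_nonsyn < 0.05 / 4
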