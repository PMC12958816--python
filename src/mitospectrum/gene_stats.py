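"""Per-gene and per-ETC-complex polymorphism rates and heterogeneity tests.

For each protein gene (or complex) the observed total, synonymous and
nonsynonymous SNP counts are compared with the expectation under a
homogeneous mutation frequency — the genome-wide count apportioned by the
gene's share of the matching site total (synonymous sites for synonymous
counts, and so on) — with a 1-d.f. G-test of gene vs rest-of-genome.  The
nonsynonymous/synonymous balance is tested with Fisher's exact test on the
2x2 (syn, nonsyn) x (gene, rest) table.  Bonferroni control uses the
family size (number of genes or complexes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .mito_model import AnnotatedVariant, CircularGenome, count_syn_nonsyn_sites


def g_test(observed, expected) -> tuple[float, int, float]:
    """Log-likelihood ratio (G) goodness-of-fit test.

    G = 2 sum O ln(O/E) with 0 ln 0 = 0; p is asymptotic chi-square with
    len(observed)-1 degrees of freedom.  Expected must be positive wherever
    observed is.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if (o < 0).any() or (e < 0).any():
        raise ValueError("negative counts")
    if ((e == 0) & (o > 0)).any():
        raise ValueError("expected = 0 where observed > 0")
    mask = o > 0
    G = 2.0 * float((o[mask] * np.log(o[mask] / e[mask])).sum())
    dof = int(o.size - 1)
    return G, dof, float(stats.chi2.sf(G, dof))


def g_test_2x2(table) -> tuple[float, int, float]:
    """G-test of independence on a 2x2 table (1 d.f.)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    e = stats.contingency.expected_freq(t)
    mask = t > 0
    G = 2.0 * float((t[mask] * np.log(t[mask] / e[mask])).sum())
    return G, 1, float(stats.chi2.sf(G, 1))


@dataclass
class GeneStatRow:
    """Polymorphism statistics for one gene or ETC complex."""
    name: str
    length: int
    syn_sites: float
    nonsyn_sites: float
    syn_count: int
    nonsyn_count: int
    total_rate: float
    syn_rate: float
    nonsyn_rate: float
    ns_ratio: float
    g_total: float
    p_total: float
    g_syn: float
    p_syn: float
    g_nonsyn: float
    p_nonsyn: float
    fisher_p: float
    bonferroni_alpha: float

    @property
    def total_count(self) -> int:
        return self.syn_count + self.nonsyn_count

    def significant(self, which: str = "total") -> bool:
        p = {"total": self.p_total, "syn": self.p_syn,
             "nonsyn": self.p_nonsyn, "ns": self.fisher_p}[which]
        return p < self.bonferroni_alpha


def _coding_snp_counts(variants: Iterable[AnnotatedVariant]
                       ) -> dict[str, list[int]]:
    """gene -> [synonymous, nonsynonymous] SNP counts."""
    counts: dict[str, list[int]] = {}
    for v in variants:
        if not v.is_snp or v.effect not in ("synonymous", "nonsynonymous"):
            continue
        row = counts.setdefault(v.site_class.gene, [0, 0])
        row[0 if v.effect == "synonymous" else 1] += 1
    return counts


def _stat_rows(groups: dict[str, dict], alpha: float = 0.05,
               weight_by_sites: bool = True) -> list[GeneStatRow]:
    """Shared G-test/Fisher machinery for gene- and complex-level tables.

    ``groups`` maps name -> dict(length, S, N, syn, nonsyn).  The expected
    count for a group is the genome total times the group's share of the
    matching site total (or of raw length when ``weight_by_sites`` is
    False).
    """
    names = sorted(groups)
    tot_syn = sum(groups[n]["syn"] for n in names)
    tot_nonsyn = sum(groups[n]["nonsyn"] for n in names)
    tot_S = sum(groups[n]["S"] for n in names)
    tot_N = sum(groups[n]["N"] for n in names)
    tot_len = sum(groups[n]["length"] for n in names)
    bonf = alpha / len(names)

    rows = []
    for n in names:
        g = groups[n]
        if g["S"] + g["N"] == 0:
            continue
        if weight_by_sites:
            share_tot = (g["S"] + g["N"]) / (tot_S + tot_N)
            share_syn = g["S"] / tot_S
            share_nonsyn = g["N"] / tot_N
        else:
            share_tot = share_syn = share_nonsyn = g["length"] / tot_len

        def one_test(obs, total, share):
            # gene vs rest-of-genome, expectation from the site share
            o = [obs, total - obs]
            e = [total * share, total * (1 - share)]
            if total == 0:
                return 0.0, 1.0
            G, _, p = g_test(o, e)
            return G, p

        g_tot, p_tot = one_test(g["syn"] + g["nonsyn"], tot_syn + tot_nonsyn,
                                share_tot)
        g_syn, p_syn = one_test(g["syn"], tot_syn, share_syn)
        g_non, p_non = one_test(g["nonsyn"], tot_nonsyn, share_nonsyn)
        _, fisher_p = stats.fisher_exact(
            [[g["syn"], g["nonsyn"]],
             [tot_syn - g["syn"], tot_nonsyn - g["nonsyn"]]],
            alternative="two-sided")

        rows.append(GeneStatRow(
            name=n, length=g["length"], syn_sites=g["S"], nonsyn_sites=g["N"],
            syn_count=g["syn"], nonsyn_count=g["nonsyn"],
            total_rate=(g["syn"] + g["nonsyn"]) / (g["S"] + g["N"]),
            syn_rate=g["syn"] / g["S"] if g["S"] else math.nan,
            nonsyn_rate=g["nonsyn"] / g["N"] if g["N"] else math.nan,
            ns_ratio=g["nonsyn"] / g["syn"] if g["syn"] else math.inf,
            g_total=g_tot, p_total=p_tot, g_syn=g_syn, p_syn=p_syn,
            g_nonsyn=g_non, p_nonsyn=p_non, fisher_p=float(fisher_p),
            bonferroni_alpha=bonf))
    return rows


def per_gene_table(variants: Iterable[AnnotatedVariant],
                   genome: CircularGenome, alpha: float = 0.05,
                   weight_by_sites: bool = True) -> list[GeneStatRow]:
    """Per-gene polymorphism rates with G-tests and Fisher N/S tests.

    Genes with zero countable sites are excluded.  The Bonferroni
    threshold is ``alpha`` divided by the number of genes tested.
    """
    counts = _coding_snp_counts(variants)
    groups = {}
    for gene in genome.protein_genes():
        cds = genome.cds(gene)
        S, N = count_syn_nonsyn_sites(cds, genome.code_id)
        syn, nonsyn = counts.get(gene.name, (0, 0))
        groups[gene.name] = {"length": gene.length(len(genome)),
                             "S": S, "N": N, "syn": syn, "nonsyn": nonsyn}
    return _stat_rows(groups, alpha=alpha, weight_by_sites=weight_by_sites)


def complex_table(variants: Iterable[AnnotatedVariant],
                  genome: CircularGenome, alpha: float = 0.05,
                  weight_by_sites: bool = True) -> list[GeneStatRow]:
    """Same tests with protein genes aggregated by ETC complex."""
    counts = _coding_snp_counts(variants)
    groups: dict[str, dict] = {}
    for gene in genome.protein_genes():
        if gene.complex_ is None:
            raise ValueError(f"protein gene {gene.name} lacks a complex label")
        cds = genome.cds(gene)
        S, N = count_syn_nonsyn_sites(cds, genome.code_id)
        syn, nonsyn = counts.get(gene.name, (0, 0))
        g = groups.setdefault(gene.complex_,
                              {"length": 0, "S": 0.0, "N": 0.0,
                               "syn": 0, "nonsyn": 0})
        g["length"] += gene.length(len(genome))
        g["S"] += S
        g["N"] += N
        g["syn"] += syn
        g["nonsyn"] += nonsyn
    if len(groups) < 2:
        raise ValueError("between-complex tests need at least two complexes")
    return _stat_rows(groups, alpha=alpha, weight_by_sites=weight_by_sites)
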