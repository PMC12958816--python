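"""Sequence-context analyses of synonymous polymorphism.

Three views of local context: enrichment of 5'/3' flanking nucleotides
around synonymous variants relative to the flank composition of all sites
of the same degeneracy class; the across-gene correlation between
synonymous polymorphism density and G+C content at codon positions 1+2;
and in-frame 9-bp (3-codon) sliding windows of synonymous polymorphism and
A+T content anchored at gene starts and stops.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .mito_model import AnnotatedVariant, CircularGenome, classify_site

log = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass
class NeighborTable:
    """Flanking-base counts around synonymous variants of one degeneracy class.

    ``observed[side][base]`` counts variant flanks; ``background[side][base]``
    counts flanks of *all* genomic sites of the class, the composition
    against which enrichment is judged.
    """
    degeneracy: str
    observed: dict[str, dict[str, int]]
    background: dict[str, dict[str, int]]

    def normalized(self, side: str) -> dict[str, float]:
        """Observed flank frequencies divided by background composition,
        rescaled to sum to 1 (empty result for a class with no variants)."""
        obs = self.observed[side]
        bkg = self.background[side]
        total_b = sum(bkg.values())
        if total_b == 0 or sum(obs.values()) == 0:
            return {b: 0.0 for b in BASES}
        ratios = {}
        for b in BASES:
            ratios[b] = (obs[b] / bkg[b]) if bkg[b] else 0.0
        s = sum(ratios.values())
        return {b: (r / s if s else 0.0) for b, r in ratios.items()}

    def gc_vs_at_enrichment(self, side: str) -> float:
        """Per-site mutation probability ratio for G/C vs A/T flanks."""
        obs = self.observed[side]
        bkg = self.background[side]
        gc_rate = _safe_div(obs["G"] + obs["C"], bkg["G"] + bkg["C"])
        at_rate = _safe_div(obs["A"] + obs["T"], bkg["A"] + bkg["T"])
        return _safe_div(gc_rate, at_rate)

    def chi2_test(self, side: str) -> tuple[float, int, float]:
        """Goodness-of-fit of observed flank counts vs composition-expected."""
        obs = np.array([self.observed[side][b] for b in BASES], dtype=float)
        bkg = np.array([self.background[side][b] for b in BASES], dtype=float)
        keep = bkg > 0
        expected = bkg[keep] / bkg[keep].sum() * obs[keep].sum()
        stat, p = stats.chisquare(obs[keep], expected)
        return float(stat), int(keep.sum() - 1), float(p)


def _safe_div(a: float, b: float) -> float:
    if b == 0:
        return math.inf if a else math.nan
    return a / b


def neighbor_enrichment(variants: Iterable[AnnotatedVariant],
                        genome: CircularGenome,
                        degeneracy_class: str) -> NeighborTable:
    """Flank composition of synonymous variants vs class background.

    Flanks are the previous/next base on the coding strand with circular
    wrap (all-plus-strand genomes: the genome neighbors directly).  Only
    synonymous SNPs of the requested degeneracy class contribute; a class
    with zero variants gives an all-zero observed table, never an error.
    """
    observed = {s: {b: 0 for b in BASES} for s in ("5prime", "3prime")}
    background = {s: {b: 0 for b in BASES} for s in ("5prime", "3prime")}

    L = len(genome)
    for gene in genome.protein_genes():
        for p in gene.positions(L):
            sc = classify_site(genome, p)
            if sc.degeneracy != degeneracy_class:
                continue
            five, three = genome.base(p - 1), genome.base(p + 1)
            if gene.strand == "-":
                from .mito_model import revcomp
                five, three = revcomp(genome.base(p + 1)), revcomp(genome.base(p - 1))
            background["5prime"][five] += 1
            background["3prime"][three] += 1

    for v in variants:
        if not v.is_snp or v.effect != "synonymous":
            continue
        if v.site_class.degeneracy != degeneracy_class:
            continue
        five, three = genome.base(v.position - 1), genome.base(v.position + 1)
        observed["5prime"][five] += 1
        observed["3prime"][three] += 1

    return NeighborTable(degeneracy=degeneracy_class,
                         observed=observed, background=background)


# -- per-gene composition correlation ------------------------------------------

def gene_composition_correlation(syn_rate_per_gene: Sequence[float],
                                 gc12_per_gene: Sequence[float]
                                 ) -> tuple[float, int, float]:
    """Pearson correlation between per-gene synonymous polymorphism density
    and G+C content at codon positions 1+2.

    Returns (r, d.f. = n-2, two-sided p from the t transform); NaN r with
    p=1 when either vector has zero variance.
    """
    x = np.asarray(gc12_per_gene, dtype=float)
    y = np.asarray(syn_rate_per_gene, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired gene values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, int(x.size - 2), 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), int(x.size - 2), float(p)


def gene_gc12(genome: CircularGenome, gene_name: str) -> float:
    """G+C fraction at codon positions 1 and 2 of one protein gene."""
    gene = next(g for g in genome.protein_genes() if g.name == gene_name)
    cds = genome.cds(gene)
    cds = cds[:len(cds) - len(cds) % 3]
    sub = "".join(cds[i:i + 2] for i in range(0, len(cds), 3))
    return (sub.count("G") + sub.count("C")) / len(sub)


# -- sliding windows --------------------------------------------------------

@dataclass
class WindowSeries:
    """Pooled 3-codon (9-bp) window series from one anchor.

    ``counts[i]`` is the synonymous-variant count in window ``i`` summed
    across genes; ``at_content[i]`` the mean A+T fraction; windows run
    away from the anchor (gene start or stop).
    """
    anchor: str                      # start | stop
    counts: list[int] = field(default_factory=list)
    at_content: list[float] = field(default_factory=list)
    n_windows: int = 20

WINDOW_BP = 9


def sliding_windows(variants: Iterable[AnnotatedVariant],
                    genome: CircularGenome,
                    n_windows: int = 20) -> dict[str, WindowSeries]:
    """Synonymous polymorphism and A+T content in 9-bp in-frame windows.

    Windows are non-overlapping 3-codon blocks counted from the start codon
    and, separately, backwards from the stop end; counts are pooled across
    protein genes over the first/last ``n_windows`` windows (180 bp by
    default).  A gene contributes a window only where it is long enough;
    genes shorter than two full spans contribute to both anchors (a variant
    is counted at most once per anchor series).  Trailing partial windows
    are dropped with a log note.
    """
    syn_positions: dict[str, list[int]] = {}
    for v in variants:
        if v.is_snp and v.effect == "synonymous" and v.site_class.gene:
            syn_positions.setdefault(v.site_class.gene, []).append(v.position)

    series = {a: WindowSeries(anchor=a, counts=[0] * n_windows,
                              at_content=[0.0] * n_windows,
                              n_windows=n_windows)
              for a in ("start", "stop")}
    at_sums = {a: [0.0] * n_windows for a in ("start", "stop")}
    at_n = {a: [0] * n_windows for a in ("start", "stop")}

    L = len(genome)
    for gene in genome.protein_genes():
        positions = list(gene.positions(L))
        if gene.strand == "-":
            positions = positions[::-1]
        usable = len(positions) - len(positions) % WINDOW_BP
        if usable < len(positions):
            log.debug("gene %s: dropped %d bp partial window",
                      gene.name, len(positions) - usable)
        nwin_gene = usable // WINDOW_BP
        gene_vars = set(syn_positions.get(gene.name, ()))

        for anchor in ("start", "stop"):
            for w in range(min(n_windows, nwin_gene)):
                if anchor == "start":
                    block = positions[w * WINDOW_BP:(w + 1) * WINDOW_BP]
                else:
                    lo = len(positions) - (w + 1) * WINDOW_BP
                    block = positions[lo:lo + WINDOW_BP]
                series[anchor].counts[w] += sum(1 for p in block if p in gene_vars)
                seq = "".join(genome.base(p) for p in block)
                at_sums[anchor][w] += (seq.count("A") + seq.count("T")) / WINDOW_BP
                at_n[anchor][w] += 1

    for anchor in ("start", "stop"):
        series[anchor].at_content = [
            (at_sums[anchor][i] / at_n[anchor][i]) if at_n[anchor][i] else math.nan
            for i in range(n_windows)]
    return series
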