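"""Complement-pooled mutation spectra and their composition normalization.

Base substitutions are pooled into six strand-symmetric classes
(A/T→G/C, G/C→A/T transitions; A/T→C/G, A/T→T/A, G/C→T/A, G/C→C/G
transversions).  Raw class counts confound mutation rates with base
composition — an A+T-rich genome offers more A/T targets — so proportions
are normalized by dividing each class count by the number of its source
bases in the relevant site set, then rescaling the six quotients to sum
to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .mito_model import AnnotatedVariant

#: Canonical class order: four transversions then two transitions.
CLASSES = ("A/T->C/G", "A/T->T/A", "G/C->T/A", "G/C->C/G",
           "A/T->G/C", "G/C->A/T")
TRANSITIONS = ("A/T->G/C", "G/C->A/T")
TRANSVERSIONS = ("A/T->C/G", "A/T->T/A", "G/C->T/A", "G/C->C/G")

#: Classes that shift composition toward A/T resp. G/C; A/T->T/A and
#: G/C->C/G are composition-neutral.
AT_INCREASING = ("G/C->A/T", "G/C->T/A")
GC_INCREASING = ("A/T->G/C", "A/T->C/G")

_PAIR = {"A": "A/T", "T": "A/T", "G": "G/C", "C": "G/C"}


def substitution_class(ancestral: str, derived: str) -> str:
    """Pooled class of a single-base substitution (complement pooling)."""
    src, dst = _PAIR[ancestral.upper()], _PAIR[derived.upper()]
    if src == dst == "A/T":
        return "A/T->T/A"
    if src == dst == "G/C":
        return "G/C->C/G"
    from .genetic_code import is_transition
    if is_transition(ancestral.upper(), derived.upper()):
        return f"{src}->{dst}"
    return "A/T->C/G" if src == "A/T" else "G/C->T/A"


@dataclass
class SpectrumTable:
    """Counts of the six pooled substitution classes for one site stratum.

    ``n_at`` / ``n_gc`` are the A/T and G/C base counts of the site set the
    variants were drawn from; they are the normalization denominators.
    """
    counts: dict[str, int]
    n_at: Optional[int] = None
    n_gc: Optional[int] = None
    stratum: str = "all"
    n_filtered_indels: int = 0

    def __post_init__(self):
        full = {k: int(self.counts.get(k, 0)) for k in CLASSES}
        if any(v < 0 for v in full.values()):
            raise ValueError("negative class count")
        self.counts = full

    @classmethod
    def from_vector(cls, counts: Sequence[int], **kw) -> "SpectrumTable":
        """Build from six counts in canonical :data:`CLASSES` order."""
        return cls(dict(zip(CLASSES, counts)), **kw)

    def vector(self) -> np.ndarray:
        return np.array([self.counts[k] for k in CLASSES], dtype=float)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def _denominator(self, klass: str) -> int:
        if self.n_at is None or self.n_gc is None:
            raise ValueError("denominators not set on this SpectrumTable")
        return self.n_at if klass.startswith("A/T") else self.n_gc


def pool_substitutions(variants: Iterable[AnnotatedVariant],
                       stratifier: str = "all",
                       split_threefold: bool = False
                       ) -> dict[str, SpectrumTable]:
    """Pool SNPs into six-class tables, optionally stratified.

    ``stratifier`` is ``all``, ``codon_position`` or ``degeneracy``.
    Indels are filtered (counted on the table), never an error.  Returned
    dict maps stratum label -> table; for ``all`` the single key is
    ``"all"``.  Denominators are not set here (they depend on the genome's
    site sets; see :func:`stratum_composition`).
    """
    if stratifier not in ("all", "codon_position", "degeneracy"):
        raise ValueError(f"unknown stratifier {stratifier!r}")
    tables: dict[str, SpectrumTable] = {}
    n_indels = 0
    for v in variants:
        if not v.is_snp:
            n_indels += 1
            continue
        if stratifier == "all":
            key = "all"
        elif stratifier == "codon_position":
            if v.site_class.codon_position is None:
                continue
            key = str(v.site_class.codon_position)
        else:
            if v.site_class.degeneracy is None:
                continue
            key = v.site_class.degeneracy
        table = tables.setdefault(
            key, SpectrumTable({}, stratum=key))
        table.counts[substitution_class(v.ancestral, v.derived)] += 1
    for t in tables.values():
        t.n_filtered_indels = n_indels
    return tables


def stratum_composition(genome, stratum: str = "all",
                        degeneracy: Optional[str] = None,
                        codon_position: Optional[int] = None
                        ) -> tuple[int, int]:
    """(n_AT, n_GC) over the site set matching a stratum.

    ``stratum='all'`` counts the whole genome; degeneracy / codon-position
    strata count protein-coding sites of that class only.
    """
    from .mito_model import classify_site
    if stratum == "all" and degeneracy is None and codon_position is None:
        comp = genome.base_composition()
    else:
        positions = []
        for gene in genome.protein_genes():
            for p in gene.positions(len(genome)):
                sc = classify_site(genome, p)
                if sc.codon_position is None:
                    continue
                if degeneracy is not None and sc.degeneracy != degeneracy:
                    continue
                if codon_position is not None and sc.codon_position != codon_position:
                    continue
                positions.append(p)
        comp = genome.base_composition(positions)
    return comp["A"] + comp["T"], comp["G"] + comp["C"]


def normalize_spectrum(table: SpectrumTable) -> dict[str, float]:
    """Composition-normalized class proportions.

    p[k] = (c[k]/denom[k]) / sum_j (c[j]/denom[j]); the six proportions sum
    to 1.  Requires denominators; a zero denominator with a nonzero count
    is an error.
    """
    fracs = {}
    for k in CLASSES:
        c = table.counts[k]
        d = table._denominator(k)
        if d == 0:
            if c:
                raise ValueError(f"zero denominator with nonzero count for {k}")
            fracs[k] = 0.0
        else:
            fracs[k] = c / d
    s = sum(fracs.values())
    if s == 0:
        raise ValueError("empty spectrum cannot be normalized")
    return {k: v / s for k, v in fracs.items()}


def ts_tv(table: SpectrumTable) -> float:
    """Transition/transversion ratio.

    Returns ``math.inf`` when there are transitions but no transversions
    and ``math.nan`` for an empty table.
    """
    ts = sum(table.counts[k] for k in TRANSITIONS)
    tv = sum(table.counts[k] for k in TRANSVERSIONS)
    if ts == tv == 0:
        return math.nan
    if tv == 0:
        return math.inf
    return ts / tv


def transition_fraction(table: SpectrumTable) -> float:
    """Share of SNPs that are transitions (NaN for an empty table)."""
    if table.total == 0:
        return math.nan
    return sum(table.counts[k] for k in TRANSITIONS) / table.total


def at_gc_flux(table: SpectrumTable) -> float:
    """Ratio of A/T-increasing to G/C-increasing substitution counts.

    Composition-neutral classes (A/T->T/A, G/C->C/G) are excluded.  At
    mutational (drift) equilibrium the ratio is 1.
    """
    num = sum(table.counts[k] for k in AT_INCREASING)
    den = sum(table.counts[k] for k in GC_INCREASING)
    if den == 0:
        return math.inf if num else math.nan
    return num / den


def flux_balance_test(table: SpectrumTable) -> tuple[float, int, float]:
    """Goodness-of-fit χ² of A/T- vs G/C-increasing counts against 50:50.

    Returns (χ², d.f.=1, p).
    """
    num = sum(table.counts[k] for k in AT_INCREASING)
    den = sum(table.counts[k] for k in GC_INCREASING)
    stat, p = stats.chisquare([num, den])
    return float(stat), 1, float(p)


def compare_spectra(rows: Sequence[Sequence[float]]) -> tuple[float, int, float, int]:
    """Pearson χ² test of independence between spectra.

    ``rows`` is an R×C count table (one row per study/stratum, one column
    per substitution class).  No continuity correction.  Returns
    (χ², d.f., p, N).  Expected cells of zero raise with advice to merge
    categories.
    """
    table = np.asarray(rows, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need a 2-D table with at least two rows")
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValueError("expected cell count of 0; merge sparse categories")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p), int(table.sum())
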