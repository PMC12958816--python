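"""Domain model for circular mitochondrial genomes and variant annotation.

Coordinates are 1-based inclusive throughout, with circular arithmetic
modulo the genome length: an annotation with ``start > end`` wraps through
the origin.  All annotation logic assumes the invertebrate mitochondrial
genetic code by default (see :mod:`mitospectrum.genetic_code`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import genetic_code as gc

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTacgt-", "TGCAtgca-")

FEATURE_TYPES = ("protein", "tRNA", "rRNA", "noncoding")
ETC_COMPLEXES = ("I", "III", "IV", "V")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One feature on the circular genome, 1-based inclusive.

    ``start > end`` denotes a feature wrapping through the origin.
    ``complex_`` groups protein genes into electron transport chain
    complexes (I, III, IV, V) and must be unset for non-protein features.
    """
    name: str
    start: int
    end: int
    strand: str = "+"
    feature_type: str = "protein"
    complex_: Optional[str] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"bad feature type {self.feature_type!r}")
        if self.complex_ is not None:
            if self.feature_type != "protein":
                raise ValueError("complex set on non-protein feature")
            if self.complex_ not in ETC_COMPLEXES:
                raise ValueError(f"unknown ETC complex {self.complex_!r}")

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def positions(self, genome_length: int) -> Iterable[int]:
        """Positions 5'->3' on the plus strand of the circle."""
        if self.start <= self.end:
            return range(self.start, self.end + 1)
        return list(range(self.start, genome_length + 1)) + list(range(1, self.end + 1))

    def contains(self, position: int) -> bool:
        if self.start <= self.end:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end


@dataclass(frozen=True)
class SiteClass:
    """Classification of one genomic site.

    ``degeneracy`` is defined iff ``codon_position`` is (protein sites
    only); codon position 2 is always nondegenerate.
    """
    feature_type: str
    gene: Optional[str] = None
    codon_position: Optional[int] = None
    degeneracy: Optional[str] = None

    def __post_init__(self):
        if (self.codon_position is None) != (self.degeneracy is None):
            raise ValueError("degeneracy defined iff codon_position defined")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One polarized variant with its functional annotation."""
    position: int
    ancestral: str
    derived: str
    kind: str                 # SNP | insertion | deletion
    effect: str               # synonymous | nonsynonymous | frameshift |
                              # in-frame-indel | tRNA | rRNA | noncoding
    site_class: SiteClass
    heteroplasmic_frequency: float = 1.0
    origin: str = "terminal_branch"   # or ancestral_branch
    branch_id: Optional[str] = None

    def __post_init__(self):
        if not 0.0 <= self.heteroplasmic_frequency <= 1.0:
            raise ValueError("frequency outside [0, 1]")
        if self.kind == "SNP" and self.ancestral == self.derived:
            raise ValueError("SNP alleles identical")
        if self.origin not in ("ancestral_branch", "terminal_branch"):
            raise ValueError(f"bad origin {self.origin!r}")

    @property
    def is_snp(self) -> bool:
        return self.kind == "SNP"


class OverlapError(ValueError):
    """Raised when a position falls in two protein-coding genes."""


@dataclass
class CircularGenome:
    """A circular reference sequence with typed gene annotations."""
    sequence: str
    annotations: list[GeneAnnotation] = field(default_factory=list)
    code_id: int = gc.INVERTEBRATE_MITO
    name: str = "mtDNA"

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError("sequence must be non-empty over {A,C,G,T}")
        L = len(self.sequence)
        for a in self.annotations:
            if not (1 <= a.start <= L and 1 <= a.end <= L):
                raise ValueError(f"annotation {a.name} outside [1, {L}]")
        self._check_protein_overlap()

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based circular coordinate."""
        L = len(self.sequence)
        return self.sequence[(position - 1) % L]

    def wrap(self, position: int) -> int:
        """Normalize any integer coordinate onto [1, L]."""
        return (position - 1) % len(self.sequence) + 1

    def _check_protein_overlap(self):
        prot = [a for a in self.annotations if a.feature_type == "protein"]
        seen: dict[int, str] = {}
        for a in prot:
            for p in a.positions(len(self.sequence)):
                if p in seen:
                    raise OverlapError(
                        f"position {p} in both {seen[p]} and {a.name}")
                seen[p] = a.name

    def protein_genes(self) -> list[GeneAnnotation]:
        return [a for a in self.annotations if a.feature_type == "protein"]

    def feature_at(self, position: int) -> Optional[GeneAnnotation]:
        """The protein gene at a position if any, else any other feature."""
        hit = None
        for a in self.annotations:
            if a.contains(position):
                if a.feature_type == "protein":
                    return a
                if hit is None:
                    hit = a
        return hit

    def cds(self, gene: GeneAnnotation) -> str:
        """Coding sequence of a protein gene, 5'->3' on its coding strand.

        A trailing partial codon (truncated stop, completed by
        polyadenylation in vivo) is retained here; codon iteration simply
        ignores the incomplete tail.
        """
        L = len(self.sequence)
        seq = "".join(self.base(p) for p in gene.positions(L))
        return revcomp(seq) if gene.strand == "-" else seq

    def codon_at(self, position: int) -> tuple[GeneAnnotation, str, int, int]:
        """Return (gene, codon, codon position 1..3, codon index 0-based)
        for a position inside a protein gene.

        The codon position is counted along the coding strand.
        """
        gene = self.feature_at(position)
        if gene is None or gene.feature_type != "protein":
            raise ValueError(f"position {position} not in a protein gene")
        L = len(self.sequence)
        positions = list(gene.positions(L))
        offset = positions.index(position)
        if gene.strand == "-":
            offset = len(positions) - 1 - offset
        cds = self.cds(gene)
        idx, within = divmod(offset, 3)
        codon = cds[idx * 3:idx * 3 + 3]
        if len(codon) < 3:
            raise ValueError(
                f"position {position} in truncated terminal codon of {gene.name}")
        return gene, codon, within + 1, idx

    def base_composition(self, positions: Optional[Iterable[int]] = None) -> dict[str, int]:
        """Counts of A, C, G, T over the genome or a subset of positions."""
        if positions is None:
            seq = self.sequence
        else:
            seq = "".join(self.base(p) for p in positions)
        return {b: seq.count(b) for b in "ACGT"}


# -- site classification ---------------------------------------------------

def classify_site(genome: CircularGenome, position: int,
                  split_threefold: bool = False) -> SiteClass:
    """Classify a site by gene, codon position and degeneracy.

    Degeneracy is established by enumerating the three alternative bases at
    the site under the genome's genetic code: ``four`` iff all three are
    synonymous, ``non`` iff none is, ``two`` otherwise.
    """
    if not 1 <= position <= len(genome):
        raise IndexError(f"position {position} outside [1, {len(genome)}]")
    feature = genome.feature_at(position)
    if feature is None:
        return SiteClass(feature_type="noncoding")
    if feature.feature_type != "protein":
        return SiteClass(feature_type=feature.feature_type, gene=feature.name)
    gene, codon, codon_pos, _ = genome.codon_at(position)
    deg = gc.degeneracy_class(codon, codon_pos - 1, genome.code_id,
                              split_threefold=split_threefold)
    return SiteClass(feature_type="protein", gene=gene.name,
                     codon_position=codon_pos, degeneracy=deg)


def annotate_variant(genome: CircularGenome, position: int, ancestral: str,
                     derived: str, frequency: float = 1.0,
                     origin: str = "terminal_branch",
                     branch_id: Optional[str] = None) -> AnnotatedVariant:
    """Annotate a variant against its ancestral genome.

    SNP effects come from translating the ancestral vs derived codon.
    Indels within protein genes are frameshifts unless the length change is
    a multiple of 3; indels elsewhere are labeled by feature type.  The
    ancestral allele must match the genome at ``position`` (the genome *is*
    the ancestral sequence for this variant).
    """
    ancestral, derived = ancestral.upper(), derived.upper()
    for allele in (ancestral, derived):
        if not allele or set(allele) - set("ACGT"):
            raise ValueError(f"bad allele {allele!r}")
    L = len(genome)
    ref_context = "".join(genome.base(position + i) for i in range(len(ancestral)))
    if ref_context != ancestral:
        raise ValueError(
            f"ancestral allele {ancestral} disagrees with genome context "
            f"{ref_context} at {position}")

    if len(ancestral) == len(derived) == 1:
        kind = "SNP"
    elif len(ancestral) > len(derived):
        kind = "deletion"
    else:
        kind = "insertion"

    site = classify_site(genome, position)
    if kind == "SNP":
        if site.feature_type != "protein":
            effect = site.feature_type
        else:
            gene, codon, codon_pos, _ = genome.codon_at(position)
            base_anc, base_der = ancestral, derived
            if gene.strand == "-":
                base_anc, base_der = revcomp(base_anc), revcomp(base_der)
            assert codon[codon_pos - 1] == base_anc
            alt = codon[:codon_pos - 1] + base_der + codon[codon_pos:]
            effect = ("synonymous"
                      if gc.translate_codon(alt, genome.code_id)
                      == gc.translate_codon(codon, genome.code_id)
                      else "nonsynonymous")
    else:
        if site.feature_type == "protein":
            shift = abs(len(ancestral) - len(derived)) % 3
            effect = "frameshift" if shift else "in-frame-indel"
        else:
            effect = site.feature_type

    return AnnotatedVariant(position=position, ancestral=ancestral,
                            derived=derived, kind=kind, effect=effect,
                            site_class=site,
                            heteroplasmic_frequency=frequency,
                            origin=origin, branch_id=branch_id)


def count_syn_nonsyn_sites(cds: str, code_id: int = gc.INVERTEBRATE_MITO
                           ) -> tuple[float, float]:
    """Nei-Gojobori-style unweighted synonymous/nonsynonymous site counts.

    Each codon position contributes (number of synonymous single-base
    changes)/3 synonymous sites; changes to stop codons count as
    nonsynonymous so that S + N equals the number of bases in complete
    codons exactly.  A trailing partial codon (truncated stop) is excluded;
    codons with ambiguity characters are skipped with a logged warning.
    """
    cds = cds.upper()
    S = 0.0
    N = 0.0
    skipped = 0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if set(codon) - set("ACGT"):
            skipped += 1
            continue
        if gc.translate_codon(codon, code_id) == "*":
            raise ValueError(f"internal stop codon {codon} at CDS offset {i}")
        for pos in range(3):
            f = gc.synonymous_alternatives(codon, pos, code_id) / 3.0
            S += f
            N += 1.0 - f
    if skipped:
        log.warning("count_syn_nonsyn_sites: skipped %d ambiguous codons", skipped)
    return S, N
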