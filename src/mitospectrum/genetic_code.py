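"""Genetic-code tables and codon degeneracy logic.

The default code is the invertebrate mitochondrial code (NCBI translation
table 5), under which AGA/AGG encode serine, ATA encodes methionine and TGA
encodes tryptophan.  Codes are stored as plain ``{codon: amino acid}``
dictionaries (stop = ``*``) so that alternative tables are pluggable.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

INVERTEBRATE_MITO = 5


@lru_cache(maxsize=None)
def codon_table(code_id: int = INVERTEBRATE_MITO) -> dict[str, str]:
    """Return the codon -> amino-acid map for an NCBI translation table.

    Stop codons are mapped to ``'*'``.
    """
    table = CodonTable.unambiguous_dna_by_id[code_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def translate_codon(codon: str, code_id: int = INVERTEBRATE_MITO) -> str:
    codon = codon.upper()
    try:
        return codon_table(code_id)[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return (a in PURINES) == (b in PURINES) and a != b


def synonymous_alternatives(codon: str, position: int,
                            code_id: int = INVERTEBRATE_MITO) -> int:
    """Number of the 3 alternative bases at ``position`` (0-based within the
    codon) that leave the encoded amino acid unchanged.

    Changes that create or destroy a stop codon are never synonymous.
    """
    code = codon_table(code_id)
    aa = code[codon]
    n = 0
    for b in BASES:
        if b == codon[position]:
            continue
        alt = codon[:position] + b + codon[position + 1:]
        if code[alt] == aa and aa != "*":
            n += 1
    return n


def degeneracy_class(codon: str, position: int,
                     code_id: int = INVERTEBRATE_MITO,
                     split_threefold: bool = False) -> str:
    """Degeneracy of one codon position: ``non``, ``two`` or ``four``.

    ``four`` means every alternative base is synonymous, ``non`` means none
    is.  Sites with one or two synonymous alternatives are pooled as ``two``
    unless ``split_threefold`` is set, in which case the 2-alternative case
    is reported as ``three``.
    """
    n = synonymous_alternatives(codon, position, code_id)
    if n == 3:
        return "four"
    if n == 0:
        return "non"
    if n == 2 and split_threefold:
        return "three"
    return "two"


def codon_families(code_id: int = INVERTEBRATE_MITO) -> dict[str, dict]:
    """Partition sense codons into synonymous families split by codon box.

    A family is the set of codons sharing their first two bases and their
    amino acid; six-fold amino acids (e.g. Leu, Ser under most codes) are
    split into their separate boxes.  Each family records its degeneracy
    class: ``four`` when the whole box is synonymous, ``two`` when exactly
    two box members encode the amino acid.

    Two-fold families with A/G-ending and T/C-ending members are distinct
    families even when they share a box (e.g. ATY Ile vs ATR Met).
    """
    code = codon_table(code_id)
    families: dict[str, dict] = {}
    for first in BASES:
        for second in BASES:
            box = first + second
            by_aa: dict[str, list[str]] = {}
            for third in BASES:
                codon = box + third
                aa = code[codon]
                if aa == "*":
                    continue
                by_aa.setdefault(aa, []).append(codon)
            for aa, codons in by_aa.items():
                if len(codons) < 2:
                    continue
                size = len(codons)
                if size == 4:
                    cls = "four"
                elif size == 2:
                    cls = "two"
                else:
                    cls = "three"
                key = f"{aa}-{box}N" if size == 4 else f"{aa}-{box}{'/'.join(c[2] for c in codons)}"
                families[key] = {
                    "amino_acid": aa,
                    "box": box,
                    "codons": tuple(codons),
                    "degeneracy": cls,
                }
    return families
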