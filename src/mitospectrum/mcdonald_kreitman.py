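"""McDonald-Kreitman counts and the neutrality index.

Within-group polymorphism (Pn, Ps) and fixed differences to an outgroup
(Dn, Ds) are counted per codon column of in-frame CDS alignments.  Codons
differing at several positions are decomposed by averaging the synonymous/
nonsynonymous assignments over all minimal mutational paths (orderings of
the changed positions); paths through stop codons are excluded when any
stop-free path exists.

NI = (Pn/Ps) / (Dn/Ds).  NI > 1 indicates excess nonsynonymous
polymorphism (purifying selection keeping amino-acid variants transient),
NI < 1 excess nonsynonymous divergence (candidate positive selection).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Optional, Sequence

from scipy import stats

from . import genetic_code as gc


@dataclass
class MKCounts:
    """Polymorphism / divergence counts for one gene (or concatenation)."""
    gene: str
    Pn: float = 0.0
    Ps: float = 0.0
    Dn: float = 0.0
    Ds: float = 0.0
    skipped_columns: int = 0

    def __add__(self, other: "MKCounts") -> "MKCounts":
        return MKCounts("concatenated",
                        self.Pn + other.Pn, self.Ps + other.Ps,
                        self.Dn + other.Dn, self.Ds + other.Ds,
                        self.skipped_columns + other.skipped_columns)


def path_averaged_changes(codon_a: str, codon_b: str,
                          code_id: int = gc.INVERTEBRATE_MITO
                          ) -> tuple[float, float]:
    """(synonymous, nonsynonymous) changes between two codons, averaged over
    all minimal mutational paths.

    Paths passing through a stop codon are discarded unless every path
    does.  Identical codons give (0, 0).
    """
    code = gc.codon_table(code_id)
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if code[nxt] == "*":
                through_stop = True
            if code[nxt] == code[cur] and code[cur] != "*":
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((through_stop, syn, nonsyn))
    clean = [p for p in paths if not p[0]] or paths
    syn = sum(p[1] for p in clean) / len(clean)
    nonsyn = sum(p[2] for p in clean) / len(clean)
    return syn, nonsyn


def count_mk(ingroup: Mapping[str, str], outgroup_cds: str, gene: str = "",
             code_id: int = gc.INVERTEBRATE_MITO) -> MKCounts:
    """MK counts for one gene from aligned in-frame CDSs.

    A codon column is polymorphic when ingroup sequences differ among
    themselves: each non-majority codon contributes its path-averaged
    changes from the majority codon.  It is a fixed difference when the
    ingroup is monomorphic and differs from the outgroup.  Columns with
    gaps or ambiguity codes (in any sequence) are skipped and counted.
    """
    seqs = [s.upper() for s in ingroup.values()]
    if not seqs:
        raise ValueError("empty ingroup")
    out_seq = outgroup_cds.upper()
    lengths = {len(s) for s in seqs} | {len(out_seq)}
    if len(lengths) != 1:
        raise ValueError("CDS alignment lengths differ (frame mismatch)")
    L = lengths.pop()
    counts = MKCounts(gene=gene)
    code = gc.codon_table(code_id)

    for i in range(0, L - L % 3, 3):
        cods = [s[i:i + 3] for s in seqs]
        out_cod = out_seq[i:i + 3]
        column = cods + [out_cod]
        if any(set(c) - set("ACGT") for c in column):
            counts.skipped_columns += 1
            continue
        if any(code[c] == "*" for c in column):
            counts.skipped_columns += 1
            continue
        distinct = Counter(cods)
        major = max(sorted(distinct), key=distinct.__getitem__)
        if len(distinct) > 1:
            for cod in sorted(distinct):
                if cod == major:
                    continue
                s, n = path_averaged_changes(major, cod, code_id)
                counts.Ps += s
                counts.Pn += n
        elif major != out_cod:
            s, n = path_averaged_changes(major, out_cod, code_id)
            counts.Ds += s
            counts.Dn += n
    return counts


def neutrality_index(counts: MKCounts) -> tuple[float, float]:
    """(NI, Fisher exact two-sided p) for one MK table.

    NI = (Pn/Ps)/(Dn/Ds); NaN when a denominator is zero (flagged, no
    crash).  The Fisher test is on the 2x2 [[Pn, Ps], [Dn, Ds]] with
    counts rounded to integers.
    """
    if counts.Ps == 0 or counts.Dn == 0 or counts.Ds == 0:
        ni = math.nan
    else:
        ni = (counts.Pn / counts.Ps) / (counts.Dn / counts.Ds)
    table = [[round(counts.Pn), round(counts.Ps)],
             [round(counts.Dn), round(counts.Ds)]]
    if min(min(r) for r in table) < 0 or sum(map(sum, table)) == 0:
        return ni, math.nan
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ni, float(p)


def mk_per_gene(ingroup_by_gene: Mapping[str, Mapping[str, str]],
                outgroup_by_gene: Mapping[str, str],
                code_id: int = gc.INVERTEBRATE_MITO
                ) -> tuple[list[MKCounts], MKCounts]:
    """MK counts per gene plus the concatenated total."""
    per_gene = []
    for gene in sorted(ingroup_by_gene):
        per_gene.append(count_mk(ingroup_by_gene[gene],
                                 outgroup_by_gene[gene], gene=gene,
                                 code_id=code_id))
    total = MKCounts("concatenated")
    for c in per_gene:
        total = total + c
    return per_gene, total
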