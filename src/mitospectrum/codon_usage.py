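"""Composition-adjusted codon usage and preferred-codon selection tests.

Relative synonymous codon usage is normally computed against a uniform
expectation within each family; in an extremely A+T-rich genome that
confounds selection with composition.  Here the expected count of a codon
is its family total times the background frequency of the codon's third
base among *all* synonymous third positions of the same degeneracy class,
so a value of 1 means usage fully explained by composition.

Family-vs-rest heterogeneity of third-base composition is tested with a
Pearson chi-square whose p-value comes from Monte-Carlo resampling under
the pooled margin; the preferred-codon flux test contrasts rare vs shared
synonymous variants with a 2x2 G-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from . import genetic_code as gc
from .gene_stats import g_test_2x2
from .mito_model import AnnotatedVariant, CircularGenome

log = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass
class CodonFamily:
    """One synonymous codon family (codon box) and its observed usage."""
    name: str
    amino_acid: str
    box: str
    codons: tuple[str, ...]
    degeneracy: str                  # two | four (| three)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def third_base_counts(self) -> dict[str, int]:
        out = {b: 0 for b in BASES}
        for codon, n in self.counts.items():
            out[codon[2]] += n
        return out


def family_composition(cds_set: Mapping[str, str],
                       code_id: int = gc.INVERTEBRATE_MITO
                       ) -> list[CodonFamily]:
    """Tally codon usage per synonymous family over a set of CDSs.

    Families are codon boxes (six-fold amino acids split by box); A/G- and
    T/C-ending two-fold families are separate.  Internal stop codons raise
    with the gene and position; a trailing partial codon is ignored.
    """
    code = gc.codon_table(code_id)
    fams = gc.codon_families(code_id)
    families = [CodonFamily(name=k, amino_acid=v["amino_acid"], box=v["box"],
                            codons=v["codons"], degeneracy=v["degeneracy"],
                            counts={c: 0 for c in v["codons"]})
                for k, v in sorted(fams.items())]
    by_codon = {c: f for f in families for c in f.codons}

    for gene, cds in cds_set.items():
        cds = cds.upper()
        n_codons = len(cds) // 3
        for i in range(n_codons):
            codon = cds[3 * i:3 * i + 3]
            if set(codon) - set(BASES):
                continue
            if code[codon] == "*" and i < n_codons - 1:
                raise ValueError(
                    f"internal stop codon {codon} in {gene} at codon {i + 1}")
            fam = by_codon.get(codon)
            if fam is not None:
                fam.counts[codon] += 1
    return families


def third_position_background(families: Sequence[CodonFamily],
                              degeneracy: str) -> dict[str, float]:
    """Third-base frequencies pooled over all families of one class."""
    totals = {b: 0 for b in BASES}
    for f in families:
        if f.degeneracy != degeneracy:
            continue
        for b, n in f.third_base_counts().items():
            totals[b] += n
    s = sum(totals.values())
    if s == 0:
        return {b: math.nan for b in BASES}
    return {b: n / s for b, n in totals.items()}


def rscu_adjusted(families: Sequence[CodonFamily],
                  background: Optional[Mapping[str, Mapping[str, float]]] = None
                  ) -> dict[str, float]:
    """Composition-adjusted RSCU per codon.

    expected(codon) = family total x background frequency of the codon's
    third base among synonymous sites of the same degeneracy class,
    renormalized within the family so expected counts sum to the family
    total.  Value = observed/expected; NaN for an unused family.
    """
    if background is None:
        background = {d: third_position_background(families, d)
                      for d in {f.degeneracy for f in families}}
    out: dict[str, float] = {}
    for f in families:
        bkg = background[f.degeneracy]
        weights = {c: bkg[c[2]] for c in f.codons}
        wsum = sum(weights.values())
        for c in f.codons:
            if f.total == 0 or wsum == 0 or weights[c] == 0:
                out[c] = math.nan if f.total == 0 else (
                    math.inf if f.counts[c] else 0.0)
                continue
            expected = f.total * weights[c] / wsum
            out[c] = f.counts[c] / expected
    return out


def family_vs_rest_test(family: CodonFamily,
                        others: Sequence[CodonFamily],
                        n_sim: int = 10_000,
                        seed: int = 0,
                        alpha: float = 0.05,
                        n_families: Optional[int] = None
                        ) -> tuple[float, float, bool]:
    """Monte-Carlo Pearson chi-square: family third-base composition vs the
    pooled remainder of the same degeneracy class.

    Simulated tables keep both row totals and draw each row from the pooled
    column proportions; p = (1 + #{sim chi2 >= observed}) / (n_sim + 1).
    Returns (chi2, p_MC, significant after Bonferroni over ``n_families``).
    Zero pooled-margin categories are dropped with a log note.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rest = {b: 0 for b in BASES}
    for f in others:
        for b, n in f.third_base_counts().items():
            rest[b] += n
    fam = family.third_base_counts()

    cols = [b for b in BASES if fam[b] + rest[b] > 0]
    if len(cols) < 2:
        log.warning("family %s: fewer than 2 populated categories, merged out",
                    family.name)
        return 0.0, 1.0, False
    obs = np.array([[fam[b] for b in cols], [rest[b] for b in cols]],
                   dtype=float)

    def pearson(t):
        e = stats.contingency.expected_freq(t)
        return ((t - e) ** 2 / e).sum()

    chi2_obs = float(pearson(obs))

    rng = np.random.default_rng(seed)
    pooled = obs.sum(axis=0)
    probs = pooled / pooled.sum()
    row_tot = obs.sum(axis=1).astype(int)
    sim1 = rng.multinomial(row_tot[0], probs, size=n_sim)
    sim2 = rng.multinomial(row_tot[1], probs, size=n_sim)
    count = 0
    for i in range(n_sim):
        t = np.vstack([sim1[i], sim2[i]]).astype(float)
        if (t.sum(axis=0) == 0).any():
            count += 0 if chi2_obs > 0 else 1
            continue
        if pearson(t) >= chi2_obs - 1e-12:
            count += 1
    p_mc = (1 + count) / (n_sim + 1)
    n_fam = n_families if n_families is not None else len(others) + 1
    return chi2_obs, float(p_mc), p_mc < alpha / n_fam


def preferred_codons(families: Sequence[CodonFamily]) -> dict[str, str]:
    """family name -> most-used codon; ties broken lexicographically."""
    out = {}
    for f in families:
        if f.total == 0:
            continue
        best = max(f.counts.values())
        winners = sorted(c for c, n in f.counts.items() if n == best)
        if len(winners) > 1:
            log.warning("preferred-codon tie in %s: %s; keeping %s",
                        f.name, winners, winners[0])
        out[f.name] = winners[0]
    return out


def classify_preferred_flux(variants: Iterable[AnnotatedVariant],
                            genome: CircularGenome,
                            preferred: Mapping[str, str],
                            code_id: int = gc.INVERTEBRATE_MITO
                            ) -> dict[str, dict[str, int]]:
    """Count synonymous SNPs to / from preferred codons, split rare vs shared.

    ``rare`` = terminal-branch variants; ``shared`` = ancestral-branch
    variants.  A variant whose ancestral codon is the family's preferred
    codon is ``from``; one whose derived codon is preferred is ``to``;
    others are excluded.
    """
    if not preferred:
        raise ValueError("empty preferred-codon map")
    pref_set = set(preferred.values())
    out = {"rare": {"to": 0, "from": 0},
           "shared": {"to": 0, "from": 0}}
    for v in variants:
        if not v.is_snp or v.effect != "synonymous":
            continue
        gene, codon, cp, _ = genome.codon_at(v.position)
        anc_codon = codon
        der_codon = codon[:cp - 1] + v.derived + codon[cp:]
        group = "rare" if v.origin == "terminal_branch" else "shared"
        if der_codon in pref_set and anc_codon not in pref_set:
            out[group]["to"] += 1
        elif anc_codon in pref_set and der_codon not in pref_set:
            out[group]["from"] += 1
    return out


def preferred_flux_test(flux: Mapping[str, Mapping[str, int]]
                        ) -> tuple[float, int, float]:
    """2x2 G-test of (rare, shared) x (from-preferred, to-preferred)."""
    table = [[flux["rare"]["from"], flux["rare"]["to"]],
             [flux["shared"]["from"], flux["shared"]["to"]]]
    return g_test_2x2(table)
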