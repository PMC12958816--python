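"""Synthetic mitochondrial data with a known truth ledger.

Generates every input the analysis consumes: a circular annotated genome,
a random rooted tree with mutations placed branch-by-branch under a
configurable six-class substitution spectrum (optionally with a G/C
neighbor-context multiplier), heteroplasmic frequencies for a fraction of
terminal-branch variants, and per-isolate Poisson read-depth profiles
containing deletions/duplications.  Every stochastic choice flows from one
seeded :class:`numpy.random.Generator`, so identical seeds give identical
outputs byte for byte.

Defaults emulate the statistical structure of C. elegans mtDNA
natural-isolate data: a ~13.3 kb A+T-rich circle with 12 protein genes
grouped into ETC complexes, 22 tRNAs, 2 rRNAs and one hypervariable
control region; a transition-dominated spectrum; and a bimodal
heteroplasmic-frequency mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from . import genetic_code as gc
from .mito_model import CircularGenome, GeneAnnotation
from .spectrum import CLASSES

GAP = "-"

#: Gene complement mirroring C. elegans mtDNA (lengths rounded to codons).
DEFAULT_PROTEIN_GENES = (
    ("nd1", 873, "I"), ("atp6", 600, "V"), ("nd2", 846, "I"),
    ("cox1", 1575, "IV"), ("cox2", 696, "IV"), ("nd3", 336, "I"),
    ("nd5", 1581, "I"), ("nd6", 432, "I"), ("nd4L", 231, "I"),
    ("nd4", 1230, "I"), ("cox3", 765, "IV"), ("ctb1", 1110, "III"),
)

#: Default six-class spectrum: the composition-normalized proportions
#: estimated from natural-isolate polymorphism (canonical class order).
DEFAULT_RATES = dict(zip(CLASSES, (0.012, 0.050, 0.098, 0.006, 0.233, 0.601)))


@dataclass
class SpectrumParams:
    """Mutation-process parameters for the simulator.

    ``rates`` are relative rates of the six pooled substitution classes
    *per eligible base* (an A/T->G/C rate applies to every A or T).
    ``m_gc`` multiplies a site's mutation weight when either immediate
    circular neighbor is G or C.  ``indel_rate`` is the probability that an
    event is a 1-bp indel rather than a SNP.  ``heteroplasmic_fraction`` of
    terminal-branch events receive a frequency drawn from a bimodal mixture
    (70% Uniform(0.03, 0.30), 30% Uniform(0.70, 0.97) by default); all
    other events are homoplasmic (frequency 1).
    """
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    m_gc: float = 1.0
    indel_rate: float = 0.0
    mutations_per_branch: float = 2.0
    heteroplasmic_fraction: float = 0.066
    het_mixture: tuple = ((0.7, 0.03, 0.30), (0.3, 0.70, 0.97))

    def __post_init__(self):
        if set(self.rates) - set(CLASSES):
            raise ValueError(f"unknown class in rates: {set(self.rates) - set(CLASSES)}")
        if all(r <= 0 for r in self.rates.values()):
            raise ValueError("at least one substitution rate must be positive")
        if self.m_gc <= 0:
            raise ValueError("m_gc must be positive")

    def rate_vector(self) -> np.ndarray:
        return np.array([self.rates.get(k, 0.0) for k in CLASSES])


@dataclass(frozen=True)
class LedgerEntry:
    """One true mutation event: branch is the child-node label."""
    branch_id: str
    position: int          # 1-based reference coordinate
    ancestral: str         # '-' for insertions
    derived: str           # '-' for deletions
    frequency: float
    origin: str            # ancestral_branch / terminal_branch


@dataclass(frozen=True)
class SVTruth:
    isolate: str
    kind: str              # deletion | duplication
    start: int             # 1-based inclusive; start > end wraps the origin
    end: int
    frequency: float


@dataclass
class TruthLedger:
    entries: list[LedgerEntry] = field(default_factory=list)
    sv_truth: list[SVTruth] = field(default_factory=list)

    def snps(self) -> list[LedgerEntry]:
        return [e for e in self.entries
                if e.ancestral != GAP and e.derived != GAP]

    def consensus_entries(self) -> list[LedgerEntry]:
        """Entries visible in leaf consensus sequences (frequency >= 0.5)."""
        return [e for e in self.entries if e.frequency >= 0.5]


# -- genome -----------------------------------------------------------------

def _random_codons(rng, n, probs, code):
    """n sense (non-stop) codons drawn base-wise from ``probs``."""
    bases = np.array(list(gc.BASES))
    out = []
    while len(out) < n:
        draw = rng.choice(bases, size=3, p=probs)
        codon = "".join(draw)
        if code[codon] != "*":
            out.append(codon)
    return out


def simulate_genome(n_genes: int = 12,
                    gene_lengths: Optional[Sequence[int]] = None,
                    base_composition: Sequence[float] = (0.38, 0.12, 0.12, 0.38),
                    seed: int = 0,
                    n_trna: int = 22,
                    trna_length: int = 57,
                    rrna_lengths: Sequence[int] = (697, 953),
                    control_region_length: int = 400,
                    spacer: int = 4,
                    code_id: int = gc.INVERTEBRATE_MITO) -> CircularGenome:
    """Simulate a circular annotated genome.

    ``base_composition`` is (A, C, G, T) probabilities.  Protein genes are
    stop-free under the active code with an ATG start codon; all features
    sit on the plus strand separated by short noncoding spacers, with one
    hypervariable ``control_region`` feature (the mask target for depth
    analyses).  Deterministic for a fixed seed.
    """
    probs = np.asarray(base_composition, dtype=float)
    if probs.shape != (4,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("base_composition must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    code = gc.codon_table(code_id)

    if gene_lengths is None:
        gene_lengths = [g[1] for g in DEFAULT_PROTEIN_GENES][:n_genes]
        if n_genes > len(DEFAULT_PROTEIN_GENES):
            gene_lengths += [600] * (n_genes - len(DEFAULT_PROTEIN_GENES))
    if len(gene_lengths) != n_genes:
        raise ValueError("len(gene_lengths) != n_genes")
    if any(l % 3 or l < 6 for l in gene_lengths):
        raise ValueError("protein gene lengths must be multiples of 3 (>= 6)")

    bases = np.array(list(gc.BASES))

    def random_seq(n):
        return "".join(rng.choice(bases, size=n, p=probs))

    features = []  # (name, length, type, complex)
    for i in range(n_genes):
        if i < len(DEFAULT_PROTEIN_GENES):
            name, _, cplx = DEFAULT_PROTEIN_GENES[i]
        else:
            name, cplx = f"orf{i+1}", "I"
        features.append((name, gene_lengths[i], "protein", cplx))
    for i in range(n_trna):
        features.append((f"tRNA_{i+1:02d}", trna_length, "tRNA", None))
    for i, rl in enumerate(rrna_lengths):
        features.append((f"rRNA_{i+1}", rl, "rRNA", None))
    features.append(("control_region", control_region_length, "noncoding", None))

    # deterministic interleaving: big features spread out, tRNAs between
    order = rng.permutation(len(features))
    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    cursor = 1
    for idx in order:
        name, length, ftype, cplx = features[idx]
        if ftype == "protein":
            codons = _random_codons(rng, length // 3 - 1, probs, code)
            seq = "ATG" + "".join(codons)
        else:
            seq = random_seq(length)
        annotations.append(GeneAnnotation(
            name=name, start=cursor, end=cursor + length - 1, strand="+",
            feature_type=ftype, complex_=cplx))
        parts.append(seq)
        cursor += length
        parts.append(random_seq(spacer))
        cursor += spacer

    return CircularGenome(sequence="".join(parts), annotations=annotations,
                          code_id=code_id, name="synthetic_mtDNA")


# -- tree and mutations -------------------------------------------------------

def _build_yule_tree(rng, n_taxa: int, outgroup: str = "outgroup") -> dendropy.Tree:
    """Random binary rooted tree: Yule splitting of ingroup tips, outgroup
    as sister to the whole ingroup.  Internal nodes get stable post-order
    labels ``nodeNN``."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node

    ingroup_root = dendropy.Node()
    out_leaf = dendropy.Node()
    root.add_child(ingroup_root)
    root.add_child(out_leaf)

    a, b = dendropy.Node(), dendropy.Node()
    ingroup_root.add_child(a)
    ingroup_root.add_child(b)
    tips = [a, b]
    while len(tips) < n_taxa:
        pick = tips[int(rng.integers(len(tips)))]
        c1, c2 = dendropy.Node(), dendropy.Node()
        pick.add_child(c1)
        pick.add_child(c2)
        tips.remove(pick)
        tips.extend([c1, c2])

    for i, tip in enumerate(tips, start=1):
        tip.taxon = tns.new_taxon(f"iso{i:04d}")
    out_leaf.taxon = tns.new_taxon(outgroup)

    for i, node in enumerate(tree.postorder_node_iter()):
        node.label = node.taxon.label if node.taxon else f"node{i:03d}"
    return tree


_PAIR_BASES = {"A/T": ("A", "T"), "G/C": ("G", "C")}
#: transition / transversion partner for each source base per class
_DERIVED = {
    "A/T->G/C": {"A": "G", "T": "C"},
    "A/T->C/G": {"A": "C", "T": "G"},
    "A/T->T/A": {"A": "T", "T": "A"},
    "G/C->A/T": {"G": "A", "C": "T"},
    "G/C->T/A": {"G": "T", "C": "A"},
    "G/C->C/G": {"G": "C", "C": "G"},
}


def simulate_tree_and_mutations(genome: CircularGenome, n_taxa: int,
                                params: SpectrumParams, seed: int = 0,
                                outgroup: str = "outgroup"
                                ) -> tuple[dendropy.Tree, TruthLedger, dict[str, str]]:
    """Simulate a tree and place mutations branch by branch.

    Returns (tree with leaf labels, truth ledger, aligned leaf sequences
    keyed by leaf label).  Mutation counts per branch are Poisson with mean
    ``params.mutations_per_branch``; each event picks a class by rate, then
    a site uniformly among class-eligible bases weighted ``m_gc`` when a
    circular neighbor is G/C.  A site mutates at most once per branch.
    Leaf consensus sequences carry every event with frequency >= 0.5;
    low-frequency heteroplasmic events appear only in the ledger (and VCF).
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 ingroup taxa")
    rng = np.random.default_rng(seed)
    tree = _build_yule_tree(rng, n_taxa, outgroup=outgroup)

    L = len(genome)
    root_seq = np.array(list(genome.sequence))
    ledger = TruthLedger()
    insertions = []  # (node, position, base, frequency, origin)

    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_seq}
    rate_vec = params.rate_vector()

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node]
        child_seq = parent_seq.copy()
        is_terminal = node.is_leaf()
        origin = "terminal_branch" if is_terminal else "ancestral_branch"
        n_events = rng.poisson(params.mutations_per_branch)
        hit: set[int] = set()

        # class eligibility and context weights are taken from the branch's
        # starting sequence; the hit set forbids two events at one site on
        # one branch, so every event still sees its true ancestral base
        weights = _site_weights(child_seq, params, L)
        class_mass_base = weights.sum(axis=1) * rate_vec

        for _ in range(n_events):
            freq = 1.0
            if is_terminal and rng.random() < params.heteroplasmic_fraction:
                w, lo, hi = params.het_mixture[
                    0 if rng.random() < params.het_mixture[0][0] else 1]
                freq = float(rng.uniform(lo, hi))

            if rng.random() < params.indel_rate:
                # 1-bp indel at a uniform non-gap position
                for _try in range(1000):
                    pos = int(rng.integers(L))
                    if pos in hit or child_seq[pos] == GAP:
                        continue
                    break
                else:
                    continue
                hit.add(pos)
                if rng.random() < 0.5:   # deletion
                    anc = str(child_seq[pos])
                    ledger.entries.append(LedgerEntry(
                        node.label, pos + 1, anc, GAP, freq, origin))
                    if freq >= 0.5:
                        child_seq[pos] = GAP
                else:                     # insertion after pos
                    base = str(rng.choice(list("ACGT")))
                    ledger.entries.append(LedgerEntry(
                        node.label, pos + 1, GAP, base, freq, origin))
                    insertions.append((node, pos, base, freq, origin))
                continue

            # SNP: class by rate, site by eligibility * context weight
            if class_mass_base.sum() == 0:
                break
            k = int(rng.choice(6, p=class_mass_base / class_mass_base.sum()))
            w = weights[k].copy()
            w[list(hit)] = 0.0
            if w.sum() == 0:
                continue
            pos = int(rng.choice(L, p=w / w.sum()))
            hit.add(pos)
            anc = str(child_seq[pos])
            der = _DERIVED[CLASSES[k]][anc]
            ledger.entries.append(LedgerEntry(
                node.label, pos + 1, anc, der, freq, origin))
            if freq >= 0.5:
                child_seq[pos] = der

        seqs[node] = child_seq

    leaf_seqs = {node.label: "".join(seqs[node])
                 for node in tree.leaf_node_iter()}

    # splice insertion columns (reference-coordinate order, stable)
    if insertions:
        leaf_nodes = list(tree.leaf_node_iter())
        descendant = {}
        for node, pos, base, freq, origin in insertions:
            descendant[(node.label, pos)] = {
                l.label for l in node.leaf_iter()} if freq >= 0.5 else set()
        cols = sorted(insertions, key=lambda t: (t[1], t[0].label))
        out = {l.label: list(leaf_seqs[l.label]) for l in leaf_nodes}
        for node, pos, base, freq, origin in reversed(cols):
            carriers = descendant[(node.label, pos)]
            for label in out:
                out[label].insert(pos + 1, base if label in carriers else GAP)
        leaf_seqs = {k: "".join(v) for k, v in out.items()}

    return tree, ledger, leaf_seqs


def _site_weights(seq: np.ndarray, params: SpectrumParams, L: int) -> np.ndarray:
    """(6, L) per-class site weights for the current sequence state."""
    is_at = (seq == "A") | (seq == "T")
    is_gc = (seq == "G") | (seq == "C")
    left = np.roll(is_gc, 1)
    right = np.roll(is_gc, -1)
    context = np.where(left | right, params.m_gc, 1.0)
    weights = np.zeros((6, L))
    for k, klass in enumerate(CLASSES):
        eligible = is_at if klass.startswith("A/T") else is_gc
        weights[k] = eligible * context
    return weights


def replay_ledger(genome: CircularGenome, tree: dendropy.Tree,
                  ledger: TruthLedger) -> dict[str, str]:
    """Independent reconstruction of leaf sequences from the ledger.

    Applies consensus-visible events (frequency >= 0.5) along each
    root-to-leaf path; insertion columns are spliced exactly as the
    simulator does.  Used as the replay oracle for the simulator.
    """
    by_branch: dict[str, list[LedgerEntry]] = {}
    for e in ledger.consensus_entries():
        by_branch.setdefault(e.branch_id, []).append(e)

    L = len(genome)
    seqs = {tree.seed_node: list(genome.sequence)}
    insertions = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        seq = list(seqs[node.parent_node])
        for e in by_branch.get(node.label, ()):
            if e.derived == GAP:
                seq[e.position - 1] = GAP
            elif e.ancestral == GAP:
                insertions.append((node, e.position - 1, e.derived))
            else:
                seq[e.position - 1] = e.derived
        seqs[node] = seq

    leaf_seqs = {n.label: list(seqs[n]) for n in tree.leaf_node_iter()}
    cols = sorted(insertions, key=lambda t: (t[1], t[0].label))
    for node, pos, base in reversed(cols):
        carriers = {l.label for l in node.leaf_iter()}
        for label in leaf_seqs:
            leaf_seqs[label].insert(pos + 1, base if label in carriers else GAP)
    return {k: "".join(v) for k, v in leaf_seqs.items()}


# -- depth profiles ----------------------------------------------------------

def simulate_depth_profile(genome: CircularGenome,
                           sv_truth: Sequence[SVTruth],
                           mean_depth: float = 1000.0,
                           seed: int = 0,
                           mappability_amplitude: float = 0.0) -> np.ndarray:
    """Per-position Poisson read depth for one isolate.

    Expected depth is ``mean_depth * (1 - f)`` inside deletions,
    ``mean_depth * (1 + f)`` inside duplications and ``mean_depth``
    elsewhere, optionally modulated by a smooth mappability curve (shared
    across isolates when the same genome/amplitude is used, since it is a
    deterministic function of position).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    L = len(genome)
    factor = np.ones(L)
    covered = np.zeros(L, dtype=bool)
    for sv in sv_truth:
        if not 0.0 <= sv.frequency <= 1.0:
            raise ValueError("SV frequency outside [0, 1]")
        idx = _circular_index(sv.start, sv.end, L)
        if covered[idx].any():
            raise ValueError("overlapping SVs in one isolate")
        covered[idx] = True
        factor[idx] = (1 - sv.frequency if sv.kind == "deletion"
                       else 1 + sv.frequency)
    mapp = 1.0
    if mappability_amplitude:
        x = np.arange(L)
        mapp = 1.0 + mappability_amplitude * np.sin(2 * np.pi * x / L * 3)
    rng = np.random.default_rng(seed)
    return rng.poisson(mean_depth * factor * mapp)


def _circular_index(start: int, end: int, L: int) -> np.ndarray:
    """0-based index array for a 1-based inclusive circular interval."""
    if start <= end:
        return np.arange(start - 1, end)
    return np.concatenate([np.arange(start - 1, L), np.arange(0, end)])


def ledger_vcf_records(ledger: TruthLedger, genome: CircularGenome):
    """Ledger entries as minimal-VCF tuples (pos, ref, alt, info).

    Indels are left-anchored on the preceding reference base.
    """
    recs = []
    for e in ledger.entries:
        info = {"AF": f"{e.frequency:.4f}", "BRANCH": e.branch_id,
                "ORIGIN": e.origin}
        if e.ancestral != GAP and e.derived != GAP:
            recs.append((e.position, e.ancestral, e.derived, info))
        elif e.derived == GAP:  # deletion of 1 bp
            anchor = genome.base(e.position - 1)
            recs.append((e.position - 1, anchor + e.ancestral, anchor, info))
        else:                    # insertion after position
            anchor = genome.base(e.position)
            recs.append((e.position, anchor, anchor + e.derived, info))
    return recs
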