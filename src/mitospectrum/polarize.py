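"""Mitotype clustering, parsimony ancestral reconstruction and mutation
cataloging.

Ancestral states are reconstructed with Fitch parsimony over the 5-letter
alphabet {A, C, G, T, -} (the alignment gap is a proper state so 1-bp
indels are polarized like substitutions).  Ties are broken toward the
outgroup state at the root and toward the parent state below it, then
lexicographically, which makes the reconstruction fully deterministic.
Externally reconstructed ancestor sequences (e.g. from a probabilistic
indel-aware method) can be supplied instead via
:func:`attach_ancestral_states`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy

ALPHABET = "ACGT-"
_ORDER = {c: i for i, c in enumerate(ALPHABET)}


# -- mitotype clustering -----------------------------------------------------

def cluster_mitotypes(sequences: Mapping[str, str]
                      ) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Group identical (100% match) sequences into mitotypes.

    Returns (mitotype representative -> member isolate names,
    isolate -> representative).  The representative is the
    lexicographically first member, making the partition deterministic.
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    groups: dict[str, list[str]] = defaultdict(list)
    for name in sorted(sequences):
        groups[sequences[name].upper()].append(name)
    reps = {members[0]: members for members in groups.values()}
    member_of = {m: rep for rep, members in reps.items() for m in members}
    return reps, member_of


# -- ancestral reconstruction -------------------------------------------------

@dataclass
class PhylogenyWithStates:
    """Rooted binary tree whose nodes carry sequences.

    Leaves hold observed consensus sequences; internal nodes hold
    reconstructed states.  ``parsimony_score`` is the total number of
    implied state changes (the Fitch score summed over sites).
    """
    tree: dendropy.Tree
    states: dict[str, str]           # node label -> sequence
    outgroup: str
    parsimony_score: int = 0


def _check_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        n = len(node.child_nodes())
        if n not in (0, 2):
            raise ValueError(f"non-binary node {node.label!r} with {n} children")


def _label_nodes(tree: dendropy.Tree) -> None:
    """Stable post-order labels for unlabeled internal nodes."""
    for i, node in enumerate(tree.postorder_node_iter()):
        if node.taxon is not None:
            node.label = node.taxon.label
        elif not node.label:
            node.label = f"node{i:03d}"


def reconstruct_ancestors(tree: dendropy.Tree,
                          leaf_sequences: Mapping[str, str],
                          outgroup: str) -> PhylogenyWithStates:
    """Fitch parsimony reconstruction of all internal node sequences.

    The tree must be rooted and binary with every leaf named in
    ``leaf_sequences``; the total number of implied changes equals the
    Fitch parsimony score.
    """
    _check_binary(tree)
    _label_nodes(tree)
    leaves = [n for n in tree.leaf_node_iter()]
    for n in leaves:
        if n.label not in leaf_sequences:
            raise KeyError(f"no sequence for leaf {n.label!r}")
    if outgroup not in {n.label for n in leaves}:
        raise KeyError(f"outgroup {outgroup!r} is not a leaf")
    lengths = {len(leaf_sequences[n.label]) for n in leaves}
    if len(lengths) != 1:
        raise ValueError("leaf sequences must be aligned to equal length")
    L = lengths.pop()

    postorder = list(tree.postorder_node_iter())
    preorder = list(tree.preorder_node_iter())
    out_seq = leaf_sequences[outgroup].upper()

    # bottom-up Fitch sets, counting union events per site
    sets: dict[dendropy.Node, list[frozenset]] = {}
    score = 0
    for node in postorder:
        if node.is_leaf():
            seq = leaf_sequences[node.label].upper()
            sets[node] = [frozenset((c,)) for c in seq]
        else:
            a, b = node.child_nodes()
            sa, sb = sets[a], sets[b]
            cur = []
            for i in range(L):
                inter = sa[i] & sb[i]
                if inter:
                    cur.append(inter)
                else:
                    cur.append(sa[i] | sb[i])
                    score += 1
            sets[node] = cur

    # top-down assignment with deterministic tie-breaking
    states: dict[str, str] = {}

    def pick(candidates: frozenset, preferred: str) -> str:
        if preferred in candidates:
            return preferred
        return min(candidates, key=_ORDER.__getitem__)

    for node in preorder:
        if node.is_leaf():
            states[node.label] = leaf_sequences[node.label].upper()
            continue
        if node.parent_node is None:
            seq = "".join(pick(sets[node][i], out_seq[i]) for i in range(L))
        else:
            parent = states[node.parent_node.label]
            seq = "".join(pick(sets[node][i], parent[i]) for i in range(L))
        states[node.label] = seq

    return PhylogenyWithStates(tree=tree, states=states, outgroup=outgroup,
                               parsimony_score=score)


def attach_ancestral_states(tree: dendropy.Tree,
                            leaf_sequences: Mapping[str, str],
                            ancestor_sequences: Mapping[str, str],
                            outgroup: str) -> PhylogenyWithStates:
    """Wrap externally reconstructed ancestors into a PhylogenyWithStates.

    Accepts per-internal-node FASTA sequences keyed by node label, so the
    cataloging step can run on output of any external ASR tool.
    """
    _check_binary(tree)
    _label_nodes(tree)
    states = {k: v.upper() for k, v in leaf_sequences.items()}
    states.update({k: v.upper() for k, v in ancestor_sequences.items()})
    score = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        p = states[node.parent_node.label]
        c = states[node.label]
        score += sum(1 for x, y in zip(p, c) if x != y)
    return PhylogenyWithStates(tree=tree, states=states, outgroup=outgroup,
                               parsimony_score=score)


# -- mutation cataloging -------------------------------------------------------

@dataclass(frozen=True)
class BranchMutation:
    """One state change on one branch of the reconstructed phylogeny.

    For multi-column indels, ``ancestral``/``derived`` hold the merged run
    (gap-free on one side); ``position`` is the first aligned column
    (1-based).
    """
    branch_id: str
    position: int
    ancestral: str
    derived: str
    origin: str          # ancestral_branch | terminal_branch

    @property
    def is_snp(self) -> bool:
        return "-" not in self.ancestral and "-" not in self.derived \
            and len(self.ancestral) == len(self.derived) == 1


@dataclass
class MutationSet:
    mutations: list[BranchMutation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mutations)

    def by_origin(self) -> dict[str, int]:
        out = {"ancestral_branch": 0, "terminal_branch": 0}
        for m in self.mutations:
            out[m.origin] += 1
        return out

    def snps(self) -> list[BranchMutation]:
        return [m for m in self.mutations if m.is_snp]


def catalog_mutations(phylo: PhylogenyWithStates,
                      merge_adjacent_gaps: bool = True) -> MutationSet:
    """Emit one record per state change on each branch (pre-order walk).

    A change shared by a whole clade appears once, on the clade's stem
    branch; parallel changes in both children of a node yield two records.
    Adjacent same-branch gap columns are merged into single indel records
    so a 2-bp deletion is one mutation.  Substitution record count equals
    the reconstruction's parsimony score when states come from
    :func:`reconstruct_ancestors`.
    """
    ms = MutationSet()
    for node in phylo.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = phylo.states[node.parent_node.label]
        child = phylo.states[node.label]
        if len(parent) != len(child):
            raise ValueError(
                f"alignment length mismatch on branch to {node.label!r}")
        origin = "terminal_branch" if node.is_leaf() else "ancestral_branch"
        diffs = [i for i in range(len(parent)) if parent[i] != child[i]]
        i = 0
        while i < len(diffs):
            col = diffs[i]
            p, c = parent[col], child[col]
            if merge_adjacent_gaps and "-" in (p, c):
                # extend over adjacent columns with the same gap direction
                j = i
                while (j + 1 < len(diffs) and diffs[j + 1] == diffs[j] + 1
                       and ("-" in (parent[diffs[j + 1]], child[diffs[j + 1]]))
                       and (parent[diffs[j + 1]] == "-") == (p == "-")
                       and (child[diffs[j + 1]] == "-") == (c == "-")):
                    j += 1
                cols = diffs[i:j + 1]
                anc = "".join(parent[k] for k in cols)
                der = "".join(child[k] for k in cols)
                ms.mutations.append(BranchMutation(
                    node.label, col + 1, anc, der, origin))
                i = j + 1
            else:
                ms.mutations.append(BranchMutation(
                    node.label, col + 1, p, c, origin))
                i += 1
    return ms


def ledger_recovery(truth_entries, mutation_set: MutationSet,
                    exclude_branches: Sequence[str] = ()) -> tuple[int, int]:
    """(recovered, total) truth mutations found with correct polarity.

    A truth entry matches when the catalog holds a record with the same
    branch, position and ancestral -> derived alleles.  Branches in
    ``exclude_branches`` (typically the outgroup's terminal branch, whose
    changes are unpolarizable against a single outgroup) are left out of
    the denominator.
    """
    excluded = set(exclude_branches)
    truth = {(e.branch_id, e.position, e.ancestral, e.derived)
             for e in truth_entries if e.branch_id not in excluded}
    found = {(m.branch_id, m.position, m.ancestral, m.derived)
             for m in mutation_set.mutations}
    return len(truth & found), len(truth)


# -- duplicate-lineage collapsing ---------------------------------------------

def collapse_duplicate_lineages(variant_sets: Mapping[str, Sequence]
                                ) -> list[str]:
    """Retain one representative among isolates sharing parallel calls.

    ``variant_sets`` maps isolate name -> its called variants (hashable
    records) against the mitotype ancestor.  Isolates are linked when their
    variant sets intersect; in each connected component the isolate with
    the most variants is retained (ties broken by name order).  Isolates
    with disjoint sets are all retained.
    """
    names = sorted(variant_sets)
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_variant: dict = defaultdict(list)
    for n in names:
        for v in variant_sets[n]:
            by_variant[v].append(n)
    for carriers in by_variant.values():
        for other in carriers[1:]:
            ra, rb = find(carriers[0]), find(other)
            if ra != rb:
                parent[rb] = ra

    components: dict[str, list[str]] = defaultdict(list)
    for n in names:
        components[find(n)].append(n)
    retained = []
    for members in components.values():
        best = max(sorted(members), key=lambda n: len(variant_sets[n]))
        retained.append(best)
    return sorted(retained)


# -- contamination flagging -----------------------------------------------------

def flag_contamination(het_variants: Mapping[str, Sequence[tuple]],
                       homoplasmic_alleles: Mapping[str, set],
                       k: int = 3, eps: float = 0.05
                       ) -> dict[str, float]:
    """Flag isolates whose heteroplasmies look like cross-mitotype mixtures.

    ``het_variants`` maps isolate -> [(variant key, frequency), ...] of its
    heteroplasmic calls; ``homoplasmic_alleles`` maps *other* mitotypes ->
    set of homoplasmic variant keys.  An isolate is flagged when >= ``k``
    of its heteroplasmic variants match a single other mitotype's
    homoplasmic alleles with pairwise frequency spread <= ``eps``.  Returns
    flagged isolate -> inferred contaminating fraction (median frequency of
    the matching variants).
    """
    import statistics
    flagged = {}
    for isolate, calls in het_variants.items():
        for mitotype, alleles in homoplasmic_alleles.items():
            if mitotype == isolate:
                continue
            matching = [f for v, f in calls if v in alleles]
            if len(matching) < k:
                continue
            if max(matching) - min(matching) <= eps:
                flagged[isolate] = statistics.median(matching)
                break
    return flagged
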