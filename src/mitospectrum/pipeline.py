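"""End-to-end orchestration: simulate -> polarize -> annotate -> statistics.

Each stage reads its inputs from, and writes its outputs to, a single run
directory with fixed file names, so any stage can be re-run alone and
byte-identical outputs follow from a fixed seed.  The stages are plain
functions; the command-line interface in :mod:`mitospectrum.cli` wraps
them one-to-one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as msio
from .codon_usage import (classify_preferred_flux, family_composition,
                          preferred_codons, preferred_flux_test, rscu_adjusted)
from .context import gene_composition_correlation, gene_gc12, neighbor_enrichment, sliding_windows
from .gene_stats import complex_table, per_gene_table
from .heteroplasmy_sv import DepthProfile, classify_heteroplasmy, sv_frequency
from .mcdonald_kreitman import mk_per_gene, neutrality_index
from .mito_model import AnnotatedVariant, CircularGenome, annotate_variant
from .polarize import catalog_mutations, cluster_mitotypes, reconstruct_ancestors
from .spectrum import (at_gc_flux, normalize_spectrum, pool_substitutions,
                       stratum_composition, transition_fraction, ts_tv)
from .synthetic_data import (SpectrumParams, SVTruth, ledger_vcf_records,
                             simulate_depth_profile, simulate_genome,
                             simulate_tree_and_mutations)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run (JSON-serializable)."""
    rundir: str = "run"
    seed: int = 0
    # synthetic data
    n_taxa: int = 40
    mutations_per_branch: float = 8.0
    rates: Optional[dict] = None
    m_gc: float = 1.0
    indel_rate: float = 0.02
    heteroplasmic_fraction: float = 0.066
    mean_depth: float = 1000.0
    n_cohort: int = 5
    # analysis
    het_low: float = 0.03
    het_high: float = 0.97
    bonferroni_alpha: float = 0.05
    n_sim: int = 10_000
    code_id: int = 5
    outgroup: str = "outgroup"

    def params(self) -> SpectrumParams:
        kw = {}
        if self.rates is not None:
            kw["rates"] = dict(self.rates)
        return SpectrumParams(m_gc=self.m_gc, indel_rate=self.indel_rate,
                              mutations_per_branch=self.mutations_per_branch,
                              heteroplasmic_fraction=self.heteroplasmic_fraction,
                              **kw)

    def path(self, name: str) -> Path:
        return Path(self.rundir) / name

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


# -- stage: simulate ----------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> None:
    """Generate genome, tree, mutations, depth profiles and truth files."""
    rundir = Path(cfg.rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genome = simulate_genome(seed=int(rng.integers(2 ** 31)), code_id=cfg.code_id)
    msio.write_genome(cfg.path("genome.fasta"),
                      cfg.path("genome_annotations.tsv"), genome)

    tree, ledger, leaves = simulate_tree_and_mutations(
        genome, cfg.n_taxa, cfg.params(), seed=int(rng.integers(2 ** 31)),
        outgroup=cfg.outgroup)
    msio.write_newick(cfg.path("tree.nwk"), tree)
    msio.write_fasta(cfg.path("leaves.fasta"), leaves)
    msio.write_vcf(cfg.path("truth.vcf"), genome.name,
                   ledger_vcf_records(ledger, genome))
    msio.write_intervals(
        cfg.path("ledger.tsv"),
        [dataclasses.asdict(e) for e in ledger.entries],
        ["branch_id", "position", "ancestral", "derived", "frequency", "origin"])

    # depth profiles: a few SV carriers plus an SV-free cohort
    control = next(a for a in genome.annotations if a.name == "control_region")
    L = len(genome)
    sv_truth = [
        SVTruth("sv_del_1", "deletion", 1001, 2600, 0.45),
        SVTruth("sv_del_2", "deletion", 5001, 5800, 0.79),
        SVTruth("sv_dup_1", "duplication",
                genome.wrap(L - 900), 1200, 0.54),  # origin-spanning
    ]
    ledger.sv_truth = sv_truth
    msio.write_intervals(
        cfg.path("sv_truth.tsv"),
        [dataclasses.asdict(s) for s in sv_truth],
        ["isolate", "kind", "start", "end", "frequency"])
    with open(cfg.path("mask.tsv"), "w") as fh:
        fh.write("start\tend\n")
        fh.write(f"{control.start}\t{control.end}\n")

    for sv in sv_truth:
        depth = simulate_depth_profile(genome, [sv], cfg.mean_depth,
                                       seed=int(rng.integers(2 ** 31)))
        msio.write_depth(cfg.path(f"depth_{sv.isolate}.tsv"), depth)
    for i in range(cfg.n_cohort):
        depth = simulate_depth_profile(genome, [], cfg.mean_depth,
                                       seed=int(rng.integers(2 ** 31)))
        msio.write_depth(cfg.path(f"depth_cohort{i + 1}.tsv"), depth)


# -- stage: polarize + annotate -------------------------------------------------

def _annotation_context(genome: CircularGenome, parent_seq: str) -> CircularGenome:
    """Ancestral-sequence genome for annotating one branch's mutations.

    Gap columns (from upstream indels) are patched with the reference base
    so codon context stays well-defined; the positions actually mutated on
    the branch are never gap columns.
    """
    seq = "".join(r if c == "-" else c
                  for c, r in zip(parent_seq, genome.sequence))
    return CircularGenome(sequence=seq, annotations=genome.annotations,
                          code_id=genome.code_id, name=genome.name)


def polarize_and_annotate(genome: CircularGenome, tree, leaves: dict,
                          outgroup: str,
                          frequencies: Optional[dict] = None
                          ) -> tuple[list[AnnotatedVariant], "object"]:
    """Reconstruct ancestors, catalog mutations, annotate each one.

    ``frequencies`` optionally maps (branch, position, ancestral, derived)
    -> heteroplasmic frequency (e.g. from a VCF's AF field); unlisted
    mutations are homoplasmic.  Returns (annotated variants, phylogeny with
    states).  Mutation columns are assumed to be reference coordinates
    (true for indel-free alignments).
    """
    reps, _membership = cluster_mitotypes(leaves)
    unique = {rep: leaves[rep] for rep in reps}
    if outgroup not in unique:      # outgroup may have been clustered away
        unique[outgroup] = leaves[outgroup]
    retained = set(unique)
    tree2 = tree.clone(depth=1)
    tree2.retain_taxa_with_labels(sorted(retained))
    _suppress_unifurcations(tree2)
    phylo = reconstruct_ancestors(tree2, unique, outgroup)
    ms = catalog_mutations(phylo)

    variants = []
    by_branch: dict[str, list] = {}
    for m in ms.mutations:
        by_branch.setdefault(m.branch_id, []).append(m)
    parent_of = {}
    for node in phylo.tree.preorder_node_iter():
        for child in node.child_nodes():
            parent_of[child.label] = node.label
    for branch, muts in sorted(by_branch.items()):
        ctx = _annotation_context(genome, phylo.states[parent_of[branch]])
        for m in muts:
            pos, anc, der = m.position, m.ancestral, m.derived
            if "-" in anc or "-" in der:
                # convert gap notation to anchored indel alleles
                anchor = ctx.base(pos - 1)
                if "-" in der:       # deletion
                    anc = anchor + anc.replace("-", "")
                    der = anchor
                else:                # insertion
                    anc = anchor
                    der = anchor + der.replace("-", "")
                pos = pos - 1
                anc_ctx = anc
            freq = 1.0
            if frequencies:
                freq = frequencies.get(
                    (m.branch_id, m.position, m.ancestral, m.derived), 1.0)
            try:
                v = annotate_variant(ctx, pos, anc, der, frequency=freq,
                                     origin=m.origin, branch_id=m.branch_id)
            except ValueError as exc:
                log.warning("skipping unannotatable mutation %s: %s", m, exc)
                continue
            variants.append(v)
    return variants, phylo


def _suppress_unifurcations(tree) -> None:
    tree.suppress_unifurcations()
    # dendropy can leave the root unifurcating after taxon retention
    root = tree.seed_node
    while len(root.child_nodes()) == 1:
        only = root.child_nodes()[0]
        tree.seed_node = only
        only.parent_node = None
        root = only


def stage_polarize(cfg: RunConfig) -> list[AnnotatedVariant]:
    genome = msio.read_genome(cfg.path("genome.fasta"),
                              cfg.path("genome_annotations.tsv"), cfg.code_id)
    tree = msio.read_newick(cfg.path("tree.nwk"))
    leaves = msio.read_fasta(cfg.path("leaves.fasta"))
    freqs = {}
    for rec in msio.read_vcf(cfg.path("truth.vcf")):
        info = rec["info"]
        if len(rec["ref"]) == len(rec["alt"]) == 1:
            key = (info.get("BRANCH"), rec["pos"], rec["ref"], rec["alt"])
            freqs[key] = float(info.get("AF", 1.0))
    variants, phylo = polarize_and_annotate(genome, tree, leaves,
                                            cfg.outgroup, frequencies=freqs)
    msio.write_fasta(cfg.path("ancestors.fasta"),
                     {k: v for k, v in phylo.states.items()
                      if k.startswith("node")})
    rows = [{
        "branch_id": v.branch_id, "position": v.position,
        "ancestral": v.ancestral, "derived": v.derived, "kind": v.kind,
        "effect": v.effect, "gene": v.site_class.gene or ".",
        "codon_position": v.site_class.codon_position or ".",
        "degeneracy": v.site_class.degeneracy or ".",
        "frequency": f"{v.heteroplasmic_frequency:.4f}", "origin": v.origin,
    } for v in variants]
    msio.write_intervals(cfg.path("mutations.tsv"), rows, list(rows[0]) if rows else
                         ["branch_id", "position", "ancestral", "derived",
                          "kind", "effect", "gene", "codon_position",
                          "degeneracy", "frequency", "origin"])
    return variants


def _load_variants(cfg: RunConfig, genome: CircularGenome
                   ) -> list[AnnotatedVariant]:
    from .mito_model import SiteClass
    out = []
    for row in msio.read_table(cfg.path("mutations.tsv")):
        sc = SiteClass(
            feature_type=("protein" if row["degeneracy"] != "." else
                          ("noncoding" if row["gene"] == "." else "protein")),
            gene=None if row["gene"] == "." else row["gene"],
            codon_position=(None if row["codon_position"] == "."
                            else int(row["codon_position"])),
            degeneracy=None if row["degeneracy"] == "." else row["degeneracy"])
        if sc.gene is not None and sc.codon_position is None:
            g = next(a for a in genome.annotations if a.name == sc.gene)
            sc = SiteClass(feature_type=g.feature_type, gene=sc.gene)
        out.append(AnnotatedVariant(
            position=int(row["position"]), ancestral=row["ancestral"],
            derived=row["derived"], kind=row["kind"], effect=row["effect"],
            site_class=sc, heteroplasmic_frequency=float(row["frequency"]),
            origin=row["origin"], branch_id=row["branch_id"]))
    return out


# -- statistics stages -----------------------------------------------------------

def stage_spectrum(cfg: RunConfig) -> dict:
    genome = msio.read_genome(cfg.path("genome.fasta"),
                              cfg.path("genome_annotations.tsv"), cfg.code_id)
    variants = _load_variants(cfg, genome)
    summary = {}
    all_table = pool_substitutions(variants).get("all")
    if all_table is None:
        return {"n_snps": 0}
    all_table.n_at, all_table.n_gc = stratum_composition(genome, "all")
    summary["n_snps"] = all_table.total
    summary["ts_tv_all"] = ts_tv(all_table)
    summary["transition_fraction"] = transition_fraction(all_table)
    summary["at_gc_flux_all"] = at_gc_flux(all_table)
    summary["normalized_proportions"] = normalize_spectrum(all_table)

    rows = [{"stratum": "all", **all_table.counts,
             "n_at": all_table.n_at, "n_gc": all_table.n_gc}]
    by_deg = pool_substitutions(variants, "degeneracy")
    for deg, table in sorted(by_deg.items()):
        table.n_at, table.n_gc = stratum_composition(genome, degeneracy=deg)
        rows.append({"stratum": deg, **table.counts,
                     "n_at": table.n_at, "n_gc": table.n_gc})
        if deg == "four":
            summary["ts_tv_fourfold"] = ts_tv(table)
            summary["at_gc_flux_fourfold"] = at_gc_flux(table)
    msio.write_intervals(cfg.path("spectrum.tsv"), rows, list(rows[0]))
    return summary


def stage_genestats(cfg: RunConfig) -> dict:
    genome = msio.read_genome(cfg.path("genome.fasta"),
                              cfg.path("genome_annotations.tsv"), cfg.code_id)
    variants = _load_variants(cfg, genome)
    gene_rows = per_gene_table(variants, genome, alpha=cfg.bonferroni_alpha)
    complex_rows = complex_table(variants, genome, alpha=cfg.bonferroni_alpha)
    cols = [f.name for f in dataclasses.fields(gene_rows[0])]
    msio.write_intervals(cfg.path("gene_stats.tsv"),
                         [dataclasses.asdict(r) for r in gene_rows], cols)
    msio.write_intervals(cfg.path("complex_stats.tsv"),
                         [dataclasses.asdict(r) for r in complex_rows], cols)
    syn_rates = [r.syn_rate for r in gene_rows]
    gc12 = [gene_gc12(genome, r.name) for r in gene_rows]
    r, dof, p = gene_composition_correlation(syn_rates, gc12)
    return {"n_genes": len(gene_rows),
            "syn_gc12_pearson_r": r, "syn_gc12_df": dof, "syn_gc12_p": p,
            "significant_genes": [r_.name for r_ in gene_rows
                                  if r_.significant("total")]}


def stage_codonusage(cfg: RunConfig) -> dict:
    genome = msio.read_genome(cfg.path("genome.fasta"),
                              cfg.path("genome_annotations.tsv"), cfg.code_id)
    variants = _load_variants(cfg, genome)
    cds_set = {g.name: genome.cds(g) for g in genome.protein_genes()}
    families = family_composition(cds_set, genome.code_id)
    rscu = rscu_adjusted(families)
    msio.write_intervals(
        cfg.path("codon_usage.tsv"),
        [{"codon": c, "rscu_adjusted": f"{v:.4f}"} for c, v in sorted(rscu.items())],
        ["codon", "rscu_adjusted"])
    pref = preferred_codons(families)
    # preferred-codon flux needs ancestral context per variant; the
    # reference genome stands in for it (exact when divergence is low)
    flux = classify_preferred_flux(
        [v for v in variants
         if v.is_snp and v.effect == "synonymous"
         and genome.base(v.position) == v.ancestral],
        genome, pref, genome.code_id)
    try:
        G, dof, p = preferred_flux_test(flux)
    except ValueError:
        G, dof, p = float("nan"), 1, float("nan")
    msio.write_intervals(
        cfg.path("preferred_flux.tsv"),
        [{"class": k, "to_preferred": v["to"], "from_preferred": v["from"]}
         for k, v in flux.items()],
        ["class", "to_preferred", "from_preferred"])
    return {"preferred_flux": flux, "flux_G": G, "flux_p": p}


def stage_mk(cfg: RunConfig) -> dict:
    genome = msio.read_genome(cfg.path("genome.fasta"),
                              cfg.path("genome_annotations.tsv"), cfg.code_id)
    leaves = msio.read_fasta(cfg.path("leaves.fasta"))
    out_label = cfg.outgroup
    ingroup = {k: v for k, v in leaves.items() if k != out_label}
    L = len(genome)
    ingroup_by_gene = {}
    outgroup_by_gene = {}
    for gene in genome.protein_genes():
        idx = [p - 1 for p in gene.positions(L)]
        ingroup_by_gene[gene.name] = {
            k: "".join(s[i] for i in idx) for k, s in ingroup.items()}
        outgroup_by_gene[gene.name] = "".join(leaves[out_label][i] for i in idx)
    per_gene, total = mk_per_gene(ingroup_by_gene, outgroup_by_gene,
                                  genome.code_id)
    rows = []
    for c in per_gene + [total]:
        ni, p = neutrality_index(c)
        rows.append({"gene": c.gene, "Pn": f"{c.Pn:.2f}", "Ps": f"{c.Ps:.2f}",
                     "Dn": f"{c.Dn:.2f}", "Ds": f"{c.Ds:.2f}",
                     "NI": f"{ni:.4f}", "fisher_p": f"{p:.4g}"})
    msio.write_intervals(cfg.path("mk.tsv"), rows,
                         ["gene", "Pn", "Ps", "Dn", "Ds", "NI", "fisher_p"])
    ni, p = neutrality_index(total)
    return {"NI_concatenated": ni, "NI_fisher_p": p}


def stage_svfreq(cfg: RunConfig) -> dict:
    masks = [(int(r["start"]), int(r["end"]))
             for r in msio.read_table(cfg.path("mask.tsv"))]
    cohort = []
    i = 1
    while cfg.path(f"depth_cohort{i}.tsv").exists():
        cohort.append(DepthProfile(
            f"cohort{i}", np.array(msio.read_depth(cfg.path(f"depth_cohort{i}.tsv"))),
            masks=masks))
        i += 1
    results = []
    for row in msio.read_table(cfg.path("sv_truth.tsv")):
        profile = DepthProfile(
            row["isolate"],
            np.array(msio.read_depth(cfg.path(f"depth_{row['isolate']}.tsv"))),
            masks=masks)
        f = sv_frequency(profile, row["kind"], int(row["start"]),
                         int(row["end"]), cohort)
        results.append({"isolate": row["isolate"], "kind": row["kind"],
                        "start": row["start"], "end": row["end"],
                        "true_frequency": row["frequency"],
                        "estimated_frequency": f"{f:.4f}",
                        "classification": classify_heteroplasmy(
                            f, cfg.het_low, cfg.het_high)})
    msio.write_intervals(cfg.path("sv_calls.tsv"), results,
                         ["isolate", "kind", "start", "end", "true_frequency",
                          "estimated_frequency", "classification"])
    return {"sv_calls": results}


def run_pipeline(cfg: RunConfig) -> dict:
    """simulate -> polarize -> all statistics stages -> summary.json."""
    stage_simulate(cfg)
    stage_polarize(cfg)
    summary = {"seed": cfg.seed, "n_taxa": cfg.n_taxa}
    summary["spectrum"] = stage_spectrum(cfg)
    summary["gene_stats"] = stage_genestats(cfg)
    summary["codon_usage"] = stage_codonusage(cfg)
    summary["mk"] = stage_mk(cfg)
    summary["sv"] = stage_svfreq(cfg)
    Path(cfg.path("summary.json")).write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float))
    return summary
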