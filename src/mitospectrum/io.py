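"""File formats: FASTA, annotation tables, newick, minimal VCF, depth TSV.

All tabular formats are plain tab-separated text with a header line;
coordinates are 1-based inclusive to match the rest of the package.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mito_model import CircularGenome, GeneAnnotation

ANNOTATION_COLUMNS = ("name", "start", "end", "strand", "feature_type", "complex")


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_annotations(path, annotations: Sequence[GeneAnnotation]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            w.writerow([a.name, a.start, a.end, a.strand, a.feature_type,
                        a.complex_ or "."])


def read_annotations(path) -> list[GeneAnnotation]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(GeneAnnotation(
                name=row["name"], start=int(row["start"]), end=int(row["end"]),
                strand=row["strand"], feature_type=row["feature_type"],
                complex_=None if row["complex"] in (".", "") else row["complex"]))
    return out


def write_genome(fasta_path, annotation_path, genome: CircularGenome) -> None:
    write_fasta(fasta_path, {genome.name: genome.sequence})
    write_annotations(annotation_path, genome.annotations)


def read_genome(fasta_path, annotation_path, code_id: int = 5) -> CircularGenome:
    seqs = read_fasta(fasta_path)
    if len(seqs) != 1:
        raise ValueError("reference FASTA must contain exactly one sequence")
    name, seq = next(iter(seqs.items()))
    return CircularGenome(sequence=seq, name=name, code_id=code_id,
                          annotations=read_annotations(annotation_path))


def write_newick(path, tree: dendropy.Tree) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# -- minimal VCF -----------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=1,Type=Float,Description="Heteroplasmic allele frequency">
##INFO=<ID=BRANCH,Number=1,Type=String,Description="Branch (child node) carrying the mutation">
##INFO=<ID=ORIGIN,Number=1,Type=String,Description="ancestral_branch or terminal_branch">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path, chrom: str,
              records: Iterable[tuple[int, str, str, dict]]) -> None:
    """Write (pos, ref, alt, info) records as a minimal uncompressed VCF."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for pos, ref, alt, info in sorted(records, key=lambda r: r[0]):
            info_s = ";".join(f"{k}={v}" for k, v in info.items()) or "."
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info_s}\n")


def read_vcf(path) -> list[dict]:
    """Read a minimal VCF into dicts (pos, ref, alt, info)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")[:8]
            info_d = {}
            if info != ".":
                for kv in info.split(";"):
                    k, _, v = kv.partition("=")
                    info_d[k] = v
            out.append({"chrom": chrom, "pos": int(pos), "ref": ref,
                        "alt": alt, "info": info_d})
    return out


# -- depth / interval tables ------------------------------------------------

def write_depth(path, depths: Sequence[int], isolate: str = "") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["position", "depth"])
        for i, d in enumerate(depths, start=1):
            w.writerow([i, int(d)])


def read_depth(path) -> list[int]:
    with open(path) as fh:
        return [int(row["depth"]) for row in csv.DictReader(fh, delimiter="\t")]


def write_intervals(path, rows: Sequence[dict], columns: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for r in rows:
            w.writerow([r[c] for c in columns])


def read_table(path) -> list[dict]:
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
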