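"""Genome, cluster-table, alignment and lineage-map input/output.

This module houses the shared data model for comparative-genomic context
analysis: ordered, stranded gene models grouped into replicons and genomes,
ortholog-cluster (arCOG-style) assignments with optional domain
coordinates, and per-cluster protein multiple alignments.

Conventions
-----------
* Coordinates are 1-based and inclusive (GFF3 convention).
* Gene order within a replicon is defined by start coordinate, ties broken
  by end coordinate and then gene identifier.
* Replicon topology (linear/circular) is carried on a GFF3 ``region``
  feature via the ``Is_circular=true`` attribute; default is linear.
* Protein sequences with a trailing stop ``*`` have it stripped on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class Gene:
    """A stranded gene model with its translated protein sequence."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    protein: str = ""
    index: int = -1

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class Replicon:
    """An ordered list of genes on one replicon (chromosome or plasmid)."""

    replicon_id: str
    topology: str = "linear"
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def sort_and_index(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(self.genes):
            g.index = i


@dataclass
class Genome:
    genome_id: str
    lineage: str = ""
    replicons: list[Replicon] = field(default_factory=list)

    def genes(self) -> Iterable[Gene]:
        for rep in self.replicons:
            yield from rep.genes

    def find_gene(self, gene_id: str) -> Gene:
        for g in self.genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"gene {gene_id!r} not found in genome {self.genome_id}")


@dataclass(frozen=True)
class ClusterAssignment:
    """Membership of one gene (or one domain of it) in an ortholog cluster."""

    genome_id: str
    gene_id: str
    cluster_id: str
    dom_start: int | None = None
    dom_end: int | None = None


@dataclass
class ClusterAlignment:
    """A protein multiple alignment for one ortholog cluster."""

    cluster_id: str
    sequences: list[tuple[str, str]]
    n_columns: int = 0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"{self.cluster_id}: alignment has no sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"{self.cluster_id}: ragged alignment lengths {sorted(lengths)}")
        self.n_columns = lengths.pop()

    @property
    def n_members(self) -> int:
        return len(self.sequences)

    def ungapped_lengths(self) -> list[int]:
        return [len(s) - s.count(GAP) for _, s in self.sequences]


# ---------------------------------------------------------------------------
# GFF3 + protein FASTA


def _parse_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_genome(gff3_path: str | Path, fasta_path: str | Path,
                genome_id: str | None = None, lineage: str = "") -> Genome:
    """Read a genome from a GFF3 annotation plus a protein FASTA.

    ``gene`` features define gene models (falling back to ``CDS`` when a
    file contains no ``gene`` rows); proteins are matched by the GFF3 ``ID``
    attribute.  A gene without a protein record is kept with an empty
    protein and a warning; a duplicate gene identifier is a hard error.
    """
    gff3_path = Path(gff3_path)
    if genome_id is None:
        genome_id = gff3_path.stem
    proteins = {
        rec.id: str(rec.seq).rstrip("*")
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }

    circular: set[str] = set()
    rows: list[tuple[str, str, int, int, str, str]] = []
    with open(gff3_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff3_path}: malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            attributes = _parse_attributes(attrs)
            if ftype == "region":
                if attributes.get("Is_circular", "").lower() == "true":
                    circular.add(seqid)
                continue
            if ftype in ("gene", "CDS"):
                gid = attributes.get("ID") or attributes.get("Name")
                if gid is None:
                    raise ValueError(f"{gff3_path}: feature without ID: {line!r}")
                rows.append((seqid, ftype, int(start), int(end), strand, gid))

    wanted = "gene" if any(r[1] == "gene" for r in rows) else "CDS"
    replicons: dict[str, Replicon] = {}
    seen: set[str] = set()
    for seqid, ftype, start, end, strand, gid in rows:
        if ftype != wanted:
            continue
        if gid in seen:
            raise ValueError(f"duplicate gene_id {gid!r} in {gff3_path}")
        seen.add(gid)
        protein = proteins.get(gid)
        if protein is None:
            logger.warning("gene %s in %s has no protein record; kept empty", gid, gff3_path)
            protein = ""
        rep = replicons.setdefault(
            seqid,
            Replicon(seqid, "circular" if seqid in circular else "linear"),
        )
        rep.genes.append(Gene(gid, seqid, start, end, strand, protein))

    for rep in replicons.values():
        rep.sort_and_index()
    return Genome(genome_id, lineage, [replicons[k] for k in sorted(replicons)])


def write_genome(genome: Genome, gff3_path: str | Path, fasta_path: str | Path) -> None:
    """Write a genome back to the GFF3 + protein-FASTA dialect read_genome reads.

    Output is bit-stable: replicons and genes are emitted in their stored
    (sorted) order.
    """
    with open(gff3_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for rep in genome.replicons:
            if rep.topology == "circular":
                end = max((g.end for g in rep.genes), default=1)
                gff.write(f"{rep.replicon_id}\tublcontext\tregion\t1\t{end}\t.\t+\t.\t"
                          f"ID=region_{rep.replicon_id};Is_circular=true\n")
            for g in rep.genes:
                gff.write(f"{rep.replicon_id}\tublcontext\tgene\t{g.start}\t{g.end}\t.\t"
                          f"{g.strand}\t.\tID={g.gene_id}\n")
    with open(fasta_path, "w") as fa:
        for g in genome.genes():
            if g.protein:
                fa.write(f">{g.gene_id}\n{g.protein}\n")


# ---------------------------------------------------------------------------
# Cluster assignment tables


def read_cluster_table(tsv_path: str | Path) -> list[ClusterAssignment]:
    """Read an arCOG-style TSV of cluster assignments.

    Columns: ``genome_id  gene_id  cluster_id  [dom_start  dom_end]``.
    A gene may appear on several rows (multi-domain proteins: each domain
    is a separate assignment, and such genes are fusion candidates).  Rows
    whose domain interval is inverted are rejected with a logged error.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"genome_id", "gene_id", "cluster_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{tsv_path}: missing columns {sorted(required - set(df.columns))}")
    out: list[ClusterAssignment] = []
    for row in df.itertuples(index=False):
        ds = getattr(row, "dom_start", "")
        de = getattr(row, "dom_end", "")
        dom_start = int(ds) if ds not in ("", ".") else None
        dom_end = int(de) if de not in ("", ".") else None
        if dom_start is not None and dom_end is not None and dom_start > dom_end:
            logger.error("rejected assignment %s/%s: dom_start %d > dom_end %d",
                         row.genome_id, row.gene_id, dom_start, dom_end)
            continue
        out.append(ClusterAssignment(row.genome_id, row.gene_id, row.cluster_id,
                                     dom_start, dom_end))
    return out


def write_cluster_table(assignments: list[ClusterAssignment], tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("genome_id\tgene_id\tcluster_id\tdom_start\tdom_end\n")
        for a in assignments:
            ds = "" if a.dom_start is None else str(a.dom_start)
            de = "" if a.dom_end is None else str(a.dom_end)
            fh.write(f"{a.genome_id}\t{a.gene_id}\t{a.cluster_id}\t{ds}\t{de}\n")


# ---------------------------------------------------------------------------
# Alignments and lineage maps


def read_alignment(fasta_path: str | Path, cluster_id: str | None = None) -> ClusterAlignment:
    """Read an aligned protein FASTA; '.' gaps are normalised to '-'."""
    fasta_path = Path(fasta_path)
    if cluster_id is None:
        cluster_id = fasta_path.stem
    sequences = [
        (rec.id, str(rec.seq).upper().replace(".", GAP))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    return ClusterAlignment(cluster_id, sequences)


def write_alignment(aln: ClusterAlignment, fasta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for member_id, seq in aln.sequences:
            fh.write(f">{member_id}\n{seq}\n")


def read_lineage_map(tsv_path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping genome_id to lineage label.

    Insertion order of the file is preserved (it fixes genome column order
    in phyletic reports, keeping genomes grouped by lineage).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    if not {"genome_id", "lineage"}.issubset(df.columns):
        raise ValueError(f"{tsv_path}: need columns genome_id, lineage")
    return dict(zip(df["genome_id"], df["lineage"]))


def write_lineage_map(lineage_map: dict[str, str], tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("genome_id\tlineage\n")
        for gid, lin in lineage_map.items():
            fh.write(f"{gid}\t{lin}\n")
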