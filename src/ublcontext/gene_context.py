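"""Gene-neighborhood ("guilt by association") analysis.

Conserved genomic context is a classic source of functional inference for
uncharacterized genes: a gene that repeatedly occurs next to, in an operon
with, or fused to genes of known function across independent lineages is
likely to be functionally linked to them.  This module extracts +/-k gene
windows around anchor genes, aggregates (anchor cluster, neighbor cluster)
associations across genomes with genome-level deduplication, scores them by
lineage spread, predicts operons as same-strand runs with short intergenic
gaps, flags divergently transcribed flanking genes, and reports multi-domain
(fusion) proteins from the cluster-assignment table.

Upstream/downstream is defined on replicon coordinate order, not relative
to the anchor's strand; strands are recorded so consumers can reinterpret
(real neighborhoods mix strands, e.g. divergently encoded partners).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .genome_io import ClusterAssignment, Gene, Genome, Replicon

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"


@dataclass
class Neighborhood:
    """Up to k genes on each side of an anchor, nearest first."""

    anchor: Gene
    upstream: list[Gene]
    downstream: list[Gene]
    genome_id: str

    @property
    def neighbors(self) -> list[Gene]:
        return self.upstream + self.downstream


@dataclass
class AssociationRecord:
    anchor_cluster: str
    neighbor_cluster: str
    genomes: set[str] = field(default_factory=set)
    lineages: set[str] = field(default_factory=set)
    occurrence_count: int = 0


@dataclass
class OperonPrediction:
    replicon_id: str
    member_indices: list[int]
    strand: str


@dataclass
class FusionRecord:
    gene_id: str
    genome_id: str
    domain_clusters: list[str]
    overlap_flag: bool | None = False


def extract_neighborhood(genome: Genome, anchor_gene: Gene | str, k: int = 3) -> Neighborhood:
    """Extract the +/-k gene window around an anchor in replicon gene order.

    Linear replicons truncate at the ends; circular replicons wrap around.
    On a small circular replicon where wrap-around would revisit a gene,
    each gene appears at most once and the anchor itself never appears.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(anchor_gene, str):
        anchor_gene = genome.find_gene(anchor_gene)
    replicon = None
    for rep in genome.replicons:
        if rep.replicon_id == anchor_gene.replicon_id and anchor_gene in rep.genes:
            replicon = rep
            break
    if replicon is None:
        raise ValueError(f"anchor {anchor_gene.gene_id} not found in genome {genome.genome_id}")

    n = len(replicon.genes)
    a = anchor_gene.index
    used = {a}
    upstream: list[Gene] = []
    downstream: list[Gene] = []
    if replicon.topology == "circular":
        for step in range(1, k + 1):
            i = (a - step) % n
            if i in used:
                break
            used.add(i)
            upstream.append(replicon.genes[i])
        for step in range(1, k + 1):
            i = (a + step) % n
            if i in used:
                break
            used.add(i)
            downstream.append(replicon.genes[i])
    else:
        upstream = [replicon.genes[i] for i in range(a - 1, max(a - k, 0) - 1, -1)]
        downstream = [replicon.genes[i] for i in range(a + 1, min(a + k, n - 1) + 1)]
    return Neighborhood(anchor_gene, upstream, downstream, genome.genome_id)


def count_associations(neighborhoods: list[Neighborhood],
                       assignments: list[ClusterAssignment],
                       lineage_map: dict[str, str]) -> list[AssociationRecord]:
    """Aggregate (anchor cluster, neighbor cluster) co-occurrences.

    ``genomes`` is deduplicated — a genome contributes once to the genome
    set no matter how many paralogous anchors repeat the association —
    while ``occurrence_count`` keeps the raw co-occurrence total.
    Neighbors lacking any cluster assignment are pooled under the
    ``UNASSIGNED`` pseudo-cluster.  Records are sorted by lineage count,
    then genome count (descending), then cluster ids: associations that
    recur across independent lineages rank as evolutionarily conserved.
    """
    by_gene: dict[tuple[str, str], list[str]] = defaultdict(list)
    for a in assignments:
        by_gene[(a.genome_id, a.gene_id)].append(a.cluster_id)

    records: dict[tuple[str, str], AssociationRecord] = {}
    for nb in neighborhoods:
        anchor_clusters = by_gene.get((nb.genome_id, nb.anchor.gene_id))
        if not anchor_clusters:
            raise ValueError(f"anchor {nb.anchor.gene_id} in {nb.genome_id} "
                             f"has no cluster assignment")
        for anchor_cluster in anchor_clusters:
            for neighbor in nb.neighbors:
                neighbor_clusters = by_gene.get((nb.genome_id, neighbor.gene_id), [UNASSIGNED])
                for nc in neighbor_clusters:
                    rec = records.setdefault(
                        (anchor_cluster, nc), AssociationRecord(anchor_cluster, nc))
                    rec.genomes.add(nb.genome_id)
                    rec.occurrence_count += 1

    for rec in records.values():
        rec.lineages = {lineage_map[g] for g in rec.genomes if g in lineage_map}
    return sorted(records.values(),
                  key=lambda r: (-len(r.lineages), -len(r.genomes),
                                 r.anchor_cluster, r.neighbor_cluster))


def score_lineage_conservation(record: AssociationRecord,
                               lineage_map: dict[str, str]) -> int:
    """Number of distinct lineages in which the association was observed."""
    missing = record.genomes - lineage_map.keys()
    if missing:
        raise KeyError(f"genomes without lineage mapping: {sorted(missing)}")
    return len({lineage_map[g] for g in record.genomes})


def predict_operons(replicon: Replicon, d_max: int = 100) -> list[OperonPrediction]:
    """Greedy same-strand operon prediction.

    Maximal runs of consecutive same-strand genes whose intergenic gap
    (next.start - prev.end - 1) is <= d_max; a strand switch always splits.
    On a circular replicon the first and last runs are merged when they are
    compatible across the origin.
    """
    genes = replicon.genes
    if not genes:
        return []
    runs: list[list[int]] = [[0]]
    for i in range(1, len(genes)):
        prev, cur = genes[i - 1], genes[i]
        gap = cur.start - prev.end - 1
        if cur.strand == prev.strand and gap <= d_max:
            runs[-1].append(i)
        else:
            runs.append([i])
    if (replicon.topology == "circular" and len(runs) > 1
            and genes[0].strand == genes[-1].strand):
        # gap across the origin: from the last gene's end to the first
        # gene's start, measured on the wrapped coordinate circle
        span = max(g.end for g in genes)
        wrap_gap = (genes[0].start + span) - genes[-1].end - 1
        if wrap_gap <= d_max:
            runs[0] = runs.pop() + runs[0]
    return [OperonPrediction(replicon.replicon_id, run, genes[run[0]].strand)
            for run in runs]


def flag_divergent(operon: OperonPrediction, replicon: Replicon) -> list[Gene]:
    """Genes flanking an operon in head-to-head (divergent) orientation.

    A flanking gene is divergent when its 5' end faces the operon's 5' end
    across the intergenic region: for a plus-strand operon that is a
    minus-strand gene immediately before it; for a minus-strand operon, a
    plus-strand gene immediately after it.  At the edge of a linear
    replicon only the existing side is inspected.
    """
    genes = replicon.genes
    n = len(genes)
    first, last = operon.member_indices[0], operon.member_indices[-1]
    flagged: list[Gene] = []
    if operon.strand == "+":
        i = (first - 1) % n if replicon.topology == "circular" else first - 1
        if 0 <= i < n and i not in operon.member_indices and genes[i].strand == "-":
            flagged.append(genes[i])
    else:
        i = (last + 1) % n if replicon.topology == "circular" else last + 1
        if 0 <= i < n and i not in operon.member_indices and genes[i].strand == "+":
            flagged.append(genes[i])
    return flagged


def detect_fusions(assignments: list[ClusterAssignment],
                   min_sep: int = 10) -> list[FusionRecord]:
    """Report multi-domain genes (>= 2 cluster assignments) as fusions.

    Domains are ordered by dom_start; ``overlap_flag`` is set when any two
    domains overlap by more than ``min_sep`` residues.  Genes with a
    coordinate-less assignment among several are included with
    ``overlap_flag`` unset (None) and a warning.
    """
    by_gene: dict[tuple[str, str], list[ClusterAssignment]] = defaultdict(list)
    for a in assignments:
        by_gene[(a.genome_id, a.gene_id)].append(a)

    out: list[FusionRecord] = []
    for (genome_id, gene_id), group in sorted(by_gene.items()):
        if len(group) < 2:
            continue
        if any(a.dom_start is None or a.dom_end is None for a in group):
            logger.warning("fusion candidate %s/%s has assignments without domain "
                           "coordinates; overlap not assessed", genome_id, gene_id)
            ordered = sorted(group, key=lambda a: (a.dom_start is None,
                                                   a.dom_start or 0, a.cluster_id))
            out.append(FusionRecord(gene_id, genome_id,
                                    [a.cluster_id for a in ordered], None))
            continue
        ordered = sorted(group, key=lambda a: (a.dom_start, a.dom_end, a.cluster_id))
        overlap = False
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                ov = (min(ordered[i].dom_end, ordered[j].dom_end)
                      - max(ordered[i].dom_start, ordered[j].dom_start) + 1)
                if ov > min_sep:
                    overlap = True
        out.append(FusionRecord(gene_id, genome_id,
                                [a.cluster_id for a in ordered], overlap))
    return out


def write_associations(records: list[AssociationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("anchor_cluster\tneighbor_cluster\tn_genomes\tn_lineages\t"
                 "occurrences\tgenomes\n")
        for r in records:
            fh.write(f"{r.anchor_cluster}\t{r.neighbor_cluster}\t{len(r.genomes)}\t"
                     f"{len(r.lineages)}\t{r.occurrence_count}\t"
                     f"{','.join(sorted(r.genomes))}\n")


def write_fusions(fusions: list[FusionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_id\tdomain_clusters\toverlap\n")
        for f in fusions:
            flag = "" if f.overlap_flag is None else str(f.overlap_flag).lower()
            fh.write(f"{f.genome_id}\t{f.gene_id}\t{','.join(f.domain_clusters)}\t{flag}\n")


def write_operons(operons: list[OperonPrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write("replicon_id\tstrand\tmember_indices\n")
        for op in operons:
            fh.write(f"{op.replicon_id}\t{op.strand}\t"
                     f"{','.join(map(str, op.member_indices))}\n")
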