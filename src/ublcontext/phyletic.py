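"""Phyletic patterns: cluster-by-genome presence/absence matrices.

Presence/absence profiles across a genome panel support evolutionary
reasoning about gene families — e.g. a ubiquitin-like family missing from
exactly the genomes that lack a partner enzyme, or two families with
complementary patterns suggesting non-orthologous displacement.  Presence
is binary here (copy number lives in the gene-context module).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_io import ClusterAssignment


@dataclass
class PhyleticMatrix:
    """Boolean clusters x genomes presence matrix backed by a DataFrame."""

    table: pd.DataFrame  # index = clusters, columns = genomes, dtype bool

    @property
    def clusters(self) -> list[str]:
        return list(self.table.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.table.columns)

    def is_present(self, cluster: str, genome: str) -> bool:
        return bool(self.table.at[cluster, genome])


def build_matrix(assignments: list[ClusterAssignment],
                 genomes: list[str]) -> PhyleticMatrix:
    """Build the presence/absence matrix for a fixed genome column order.

    A cell is true iff the genome has at least one assignment of the
    cluster (idempotent under duplicate assignments); genomes with no
    assignments give all-false columns.  Cluster rows are sorted for
    deterministic output.
    """
    genome_set = set(genomes)
    clusters = sorted({a.cluster_id for a in assignments})
    table = pd.DataFrame(False, index=clusters, columns=list(genomes), dtype=bool)
    for a in assignments:
        if a.genome_id not in genome_set:
            raise ValueError(f"assignment references unknown genome {a.genome_id!r}")
        table.at[a.cluster_id, a.genome_id] = True
    return PhyleticMatrix(table)


def absence_report(matrix: PhyleticMatrix,
                   cluster_set: list[str] | set[str]) -> dict[str, list[str]]:
    """Per cluster, the genomes it is absent from, in matrix genome order."""
    unknown = set(cluster_set) - set(matrix.clusters)
    if unknown:
        raise ValueError(f"unknown clusters: {sorted(unknown)}")
    out: dict[str, list[str]] = {}
    for c in sorted(cluster_set):
        row = matrix.table.loc[c]
        out[c] = [g for g in matrix.genomes if not row[g]]
    return out


def pattern_query(matrix: PhyleticMatrix,
                  required_present: set[str],
                  required_absent: set[str]) -> list[str]:
    """Clusters present in every genome of one set and absent from the other."""
    overlap = set(required_present) & set(required_absent)
    if overlap:
        raise ValueError(f"constraint sets overlap: {sorted(overlap)}")
    for g in set(required_present) | set(required_absent):
        if g not in matrix.table.columns:
            raise ValueError(f"unknown genome {g!r}")
    mask = pd.Series(True, index=matrix.table.index)
    for g in required_present:
        mask &= matrix.table[g]
    for g in required_absent:
        mask &= ~matrix.table[g]
    return [c for c in matrix.clusters if mask[c]]


def write_matrix(matrix: PhyleticMatrix, path) -> None:
    matrix.table.astype(int).to_csv(path, sep="\t", index_label="cluster_id")


def read_matrix(path) -> PhyleticMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cluster_id")
    return PhyleticMatrix(df.astype(bool))
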