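"""Consensus reconstruction and C-terminal GG/CC doublet discovery.

Small ubiquitin-like proteins (ThiS/MoaD-family sulfur carriers, SAMPs,
Pup-like modifiers) carry a functionally essential di-glycine (GG) — or, in
some halobacterial families, di-cysteine (CC) — motif at their extreme
C-terminus.  This module reconstructs a per-column consensus for each
ortholog-cluster alignment and reports small-protein families whose trimmed
consensus ends in a conserved target doublet.

The screen is deliberately simple and fully deterministic: per-column
plurality consensus, majority-gap trimming of alignment overhangs (so the
"C-terminus" is read from real sequence ends), then a conservation
threshold on the final two columns, applied only to families whose median
ungapped member length is below a small-protein cutoff (200 aa by default).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from statistics import median_low

from .genome_io import GAP, ClusterAlignment

logger = logging.getLogger(__name__)

DEFAULT_MOTIFS = frozenset({"GG", "CC"})


@dataclass(frozen=True)
class ConsensusColumn:
    """One alignment column of a consensus profile.

    ``consensus`` is the plurality residue, uppercase when its frequency
    over ALL rows (gaps included in the denominator) reaches the plurality
    threshold, lowercase when it falls short in a mostly-residue column,
    and ``-`` in a majority-gap or all-gap column.  ``conservation`` is the
    plurality-residue count divided by the number of members, so
    ``conservation <= 1 - gap_fraction`` always holds.
    """

    consensus: str
    conservation: float
    gap_fraction: float


@dataclass
class ConsensusProfile:
    cluster_id: str
    columns: list[ConsensusColumn]
    n_members: int
    median_length: int = 0

    def consensus_string(self) -> str:
        return "".join(c.consensus for c in self.columns)


@dataclass(frozen=True)
class MotifHit:
    cluster_id: str
    motif: str
    last_two_conservation: tuple[float, float]
    median_length: int
    n_members: int


def build_consensus(aln: ClusterAlignment, plurality_min: float = 0.5) -> ConsensusProfile:
    """Reconstruct the per-column plurality consensus of a cluster alignment.

    Ties between equally frequent residues are broken alphabetically so
    the output is deterministic.
    """
    if not 0 < plurality_min <= 1:
        raise ValueError("plurality_min must be in (0, 1]")
    n = aln.n_members
    columns: list[ConsensusColumn] = []
    for j in range(aln.n_columns):
        counts = Counter(seq[j] for _, seq in aln.sequences)
        n_gap = counts.pop(GAP, 0)
        gap_fraction = n_gap / n
        if not counts:
            columns.append(ConsensusColumn(GAP, 0.0, gap_fraction))
            continue
        # plurality residue; alphabetical tie-break
        residue = min(counts, key=lambda r: (-counts[r], r))
        freq = counts[residue] / n
        if freq >= plurality_min:
            consensus = residue.upper()
        elif gap_fraction > 0.5:
            consensus = GAP
        else:
            consensus = residue.lower()
        columns.append(ConsensusColumn(consensus, freq, gap_fraction))
    profile = ConsensusProfile(aln.cluster_id, columns, n)
    profile.median_length = median_low(aln.ungapped_lengths())
    return profile


def trim_terminal_gap_columns(profile: ConsensusProfile) -> ConsensusProfile:
    """Drop leading/trailing majority-gap columns (alignment overhangs).

    Interior columns are never touched.  Needed so the C-terminal doublet
    is read from real sequence ends rather than from ragged alignment
    termini contributed by a few long members.
    """
    keep = [c.gap_fraction <= 0.5 for c in profile.columns]
    if not any(keep):
        logger.warning("cluster %s: all columns are majority-gap; profile trimmed to empty",
                       profile.cluster_id)
        return ConsensusProfile(profile.cluster_id, [], profile.n_members,
                                profile.median_length)
    first, last = keep.index(True), len(keep) - 1 - keep[::-1].index(True)
    return ConsensusProfile(profile.cluster_id, profile.columns[first:last + 1],
                            profile.n_members, profile.median_length)


def detect_cterminal_doublet(profile: ConsensusProfile,
                             motifs: frozenset[str] | set[str] = DEFAULT_MOTIFS,
                             cons_min: float = 0.8) -> MotifHit | None:
    """Test whether a trimmed profile ends in a conserved target doublet.

    A hit requires the final two consensus residues to be strong (uppercase)
    consensus spelling a motif, with both columns conserved at >= cons_min.
    """
    if len(profile.columns) < 2:
        logger.info("cluster %s: profile shorter than 2 columns, no doublet test",
                    profile.cluster_id)
        return None
    c1, c2 = profile.columns[-2], profile.columns[-1]
    doublet = c1.consensus + c2.consensus
    if not doublet.isupper() or doublet not in motifs:
        return None
    if c1.conservation < cons_min or c2.conservation < cons_min:
        return None
    return MotifHit(profile.cluster_id, doublet, (c1.conservation, c2.conservation),
                    profile.median_length, profile.n_members)


def scan_clusters(alignments: list[ClusterAlignment],
                  max_len: int = 200,
                  cons_min: float = 0.8,
                  plurality_min: float = 0.5,
                  motifs: frozenset[str] | set[str] = DEFAULT_MOTIFS) -> list[MotifHit]:
    """Screen cluster alignments for small proteins with terminal GG/CC.

    Clusters whose median ungapped member length is >= ``max_len`` are
    excluded before any motif testing; remaining clusters go through
    consensus -> trim -> doublet detection.  Hits are sorted by cluster_id.
    """
    hits: list[MotifHit] = []
    for aln in alignments:
        if median_low(aln.ungapped_lengths()) >= max_len:
            continue
        profile = trim_terminal_gap_columns(build_consensus(aln, plurality_min))
        hit = detect_cterminal_doublet(profile, motifs, cons_min)
        if hit is not None:
            hits.append(hit)
    return sorted(hits, key=lambda h: h.cluster_id)


def write_hits(hits: list[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmotif\tcons1\tcons2\tmedian_len\tn_members\n")
        for h in hits:
            fh.write(f"{h.cluster_id}\t{h.motif}\t{h.last_two_conservation[0]:.4f}\t"
                     f"{h.last_two_conservation[1]:.4f}\t{h.median_length}\t{h.n_members}\n")
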