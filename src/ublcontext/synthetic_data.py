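"""Synthetic genomes, cluster families and alignments with known truth.

Everything the analysis consumes can be generated here with planted,
exactly known ground truth: genomes with a conserved gene-neighborhood
association planted at a chosen frequency, protein families with planted
conserved C-terminal doublets at a chosen conservation level, phyletic
patterns with planted absences, and gap-free alignments evolved along a
known tree under the JTT model.

Planting is deterministic by default — an association at frequency ``f``
over ``n`` genomes is placed in exactly ``ceil(f*n)`` genomes, a motif at
conservation ``c`` in exactly ``round(c*n_members)`` members — so expected
analysis outputs are exact, with a Bernoulli mode for distributional
tests.  Every generator is a pure function of its configuration and seed.

What this emulates, and what it does not: gene orders are uniform random
with independent cluster draws, so the only conserved neighborhoods are
the planted ones; real genomes have operon structure, paralog clustering
and shared ancestry that create correlated background.  Background gene
lengths are drawn uniformly on [80, 400] aa so a small-protein length
filter has both sides populated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import jtt
from .genome_io import ClusterAssignment, ClusterAlignment, Gene, Genome, Replicon
from .phylo import PhyloTree, parse_newick


@dataclass
class PlantedAssociation:
    anchor_cluster: str
    neighbor_cluster: str
    frequency: float
    max_offset: int = 3


@dataclass
class PlantedMotifFamily:
    cluster_id: str
    motif: str
    length: int
    conservation: float
    n_members: int = 20


@dataclass
class SimConfig:
    seed: int = 0
    n_genomes: int = 10
    genes_per_genome: int = 200
    n_clusters: int = 100
    planted_associations: list[PlantedAssociation] = field(default_factory=list)
    planted_motif_families: list[PlantedMotifFamily] = field(default_factory=list)
    lineage_assignment: dict[str, str] = field(default_factory=dict)
    tree_spec: str | None = None
    tree_sites: int = 0
    bernoulli: bool = False
    circular: bool = False

    def __post_init__(self) -> None:
        for pa in self.planted_associations:
            if not 0 <= pa.frequency <= 1:
                raise ValueError("association frequency must be in [0, 1]")
        for pf in self.planted_motif_families:
            if not 0 <= pf.conservation <= 1:
                raise ValueError("motif conservation must be in [0, 1]")

    def genome_ids(self) -> list[str]:
        return [f"G{i:03d}" for i in range(self.n_genomes)]

    def lineage_of(self, genome_id: str) -> str:
        # default: every genome its own lineage (most conservative ranking)
        return self.lineage_assignment.get(genome_id, f"lin_{genome_id}")


@dataclass
class Truth:
    """Exact record of what was planted, sufficient to score any analysis."""

    association_genomes: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    association_positions: dict[tuple[str, str, str], tuple[int, int]] = field(default_factory=dict)
    motif_members: dict[str, list[str]] = field(default_factory=dict)


_BACKGROUND_AA = jtt.AMINO_ACIDS


def _random_protein(rng: np.random.Generator, length: int) -> str:
    codes = rng.choice(20, size=length, p=jtt.JTT_FREQUENCIES)
    return "".join(_BACKGROUND_AA[c] for c in codes)


def generate_genomes(config: SimConfig) -> tuple[list[Genome], list[ClusterAssignment], Truth]:
    """Generate genomes with planted neighborhood associations.

    Each genome is a single replicon of ``genes_per_genome`` genes with
    background clusters drawn uniformly from the pool.  For each planted
    association the anchor cluster is placed at one random position in
    every genome, and in the planted subset of genomes the neighbor
    cluster is placed within ``max_offset`` genes of the anchor.
    """
    rng = np.random.default_rng(config.seed)
    truth = Truth()
    genomes: list[Genome] = []
    assignments: list[ClusterAssignment] = []
    pool = [f"bg{i:04d}" for i in range(config.n_clusters)]
    n_genes = config.genes_per_genome

    planted_in: dict[int, list[str]] = {}
    for pa in config.planted_associations:
        n_sel = math.ceil(pa.frequency * config.n_genomes)
        if config.bernoulli:
            chosen = [g for g in range(config.n_genomes)
                      if rng.random() < pa.frequency]
        else:
            if 0 < pa.frequency and n_sel < 1:
                n_sel = 1
            chosen = sorted(rng.choice(config.n_genomes, size=n_sel,
                                       replace=False).tolist())
        key = (pa.anchor_cluster, pa.neighbor_cluster)
        truth.association_genomes[key] = [f"G{g:03d}" for g in chosen]
        for g in chosen:
            planted_in.setdefault(g, []).append(pa.anchor_cluster)

    for gi, genome_id in enumerate(config.genome_ids()):
        clusters = [pool[c] for c in rng.integers(0, config.n_clusters, size=n_genes)]
        # place each planted anchor (in every genome) and, where this genome
        # was chosen, its neighbor nearby
        for pa in config.planted_associations:
            anchor_pos = int(rng.integers(pa.max_offset, n_genes - pa.max_offset))
            clusters[anchor_pos] = pa.anchor_cluster
            key = (pa.anchor_cluster, pa.neighbor_cluster)
            if genome_id in truth.association_genomes.get(key, []):
                offsets = [o for o in range(-pa.max_offset, pa.max_offset + 1) if o != 0]
                off = int(offsets[rng.integers(0, len(offsets))])
                clusters[anchor_pos + off] = pa.neighbor_cluster
                truth.association_positions[(genome_id, *key)] = (anchor_pos, anchor_pos + off)

        rep = Replicon(f"{genome_id}_rep1",
                       "circular" if config.circular else "linear")
        pos = 1
        for j in range(n_genes):
            aa_len = int(rng.integers(80, 401))
            gap = int(rng.integers(10, 201))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{genome_id}_g{j:04d}"
            rep.genes.append(Gene(gene_id, rep.replicon_id, pos,
                                  pos + aa_len * 3 + 2, strand,
                                  _random_protein(rng, aa_len)))
            assignments.append(ClusterAssignment(genome_id, gene_id, clusters[j]))
            pos += aa_len * 3 + 3 + gap
        rep.sort_and_index()
        genomes.append(Genome(genome_id, config.lineage_of(genome_id), [rep]))
    return genomes, assignments, truth


def generate_motif_family(cluster_id: str, n_members: int, length: int,
                          motif: str, conservation: float,
                          seed: int | np.random.Generator) -> ClusterAlignment:
    """A gap-free protein family with a planted terminal doublet.

    Exactly ``round(conservation * n_members)`` members end with the motif;
    the remaining members are resampled at the final two positions until
    they do not, so the realised conservation is exact.
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    if len(motif) != 2:
        raise ValueError("motif must be a 2-mer")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_with = int(round(conservation * n_members))
    carriers = set(rng.choice(n_members, size=n_with, replace=False).tolist())
    sequences: list[tuple[str, str]] = []
    for i in range(n_members):
        seq = _random_protein(rng, length)
        if i in carriers:
            seq = seq[:-2] + motif
        else:
            while seq[-2:] == motif:
                seq = seq[:-2] + _random_protein(rng, 2)
        sequences.append((f"{cluster_id}_m{i:03d}", seq))
    return ClusterAlignment(cluster_id, sequences)


def evolve_alignment(tree_newick: str | PhyloTree, n_sites: int,
                     seed: int | np.random.Generator,
                     cluster_id: str = "sim") -> ClusterAlignment:
    """Evolve a gap-free protein alignment along a tree under JTT.

    The root sequence is drawn from the JTT equilibrium distribution and
    mutated independently per site along each branch with transition
    probabilities ``P(t) = expm(Q t)``.  No indels are simulated.
    """
    tree = tree_newick if isinstance(tree_newick, PhyloTree) else parse_newick(tree_newick)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root_states = rng.choice(20, size=n_sites, p=jtt.JTT_FREQUENCIES)
    leaf_seqs: dict[str, np.ndarray] = {}

    def walk(node, states: np.ndarray) -> None:
        if node.is_leaf():
            leaf_seqs[node.name] = states
            return
        if node.name is not None:
            leaf_seqs[node.name] = states
        for child in node.children:
            p = jtt.transition_matrix(child.length or 0.0)
            new = states.copy()
            for s in np.unique(states):
                idx = np.nonzero(states == s)[0]
                new[idx] = rng.choice(20, size=idx.size, p=p[s])
            walk(child, new)

    walk(tree.root, root_states)
    sequences = [
        (name, "".join(jtt.AMINO_ACIDS[c] for c in leaf_seqs[name]))
        for name in sorted(leaf_seqs)
    ]
    return ClusterAlignment(cluster_id, sequences)


def generate_phyletic_pattern(n_clusters: int, genomes: list[str],
                              absences: dict[str, list[str]],
                              seed: int = 0) -> list[ClusterAssignment]:
    """Assignments realising a presence/absence pattern with planted holes.

    Every cluster is present in every genome except where ``absences``
    lists it as missing; one assignment per present cell.
    """
    out: list[ClusterAssignment] = []
    for i in range(n_clusters):
        cluster = f"pc{i:04d}"
        absent = set(absences.get(cluster, []))
        for g in genomes:
            if g not in absent:
                out.append(ClusterAssignment(g, f"{g}_{cluster}", cluster))
    return out
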