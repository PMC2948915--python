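# Methods

This note documents the models, procedures, defaults and numerical choices
behind `ublcontext`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Data model and coordinate conventions

Gene models are 1-based, inclusive intervals (GFF3 convention) on stranded
replicons; gene order within a replicon is defined by start coordinate,
with ties broken by end coordinate then gene identifier. "Upstream" and
"downstream" are defined on replicon coordinate order, **not** relative to
the anchor's strand — real Ubl neighborhoods mix strands (divergently
encoded partners are themselves informative), so strand is recorded and
left to consumers to reinterpret. Circular replicons wrap gene order; the
topology flag comes from a GFF3 `region` feature's `Is_circular=true`
attribute and drives both neighborhood wrap-around and operon merging
across the origin. Proteins with a trailing stop `*` have it stripped on
read. One gene may carry several cluster assignments (multi-domain
proteins); each is a separate row of the assignment table.

## Consensus and C-terminal doublet scan

For each alignment column the consensus is the plurality residue among
non-gap characters (ties broken alphabetically, so output is
deterministic). It is reported uppercase when its frequency over *all*
rows reaches `plurality_min`, lowercase when it falls short in a
mostly-residue column, and `-` in a majority-gap column. Conservation is
the plurality count divided by the number of members — gap rows stay in
the denominator, because a gappy column cannot be called conserved; hence
the invariant `conservation ≤ 1 − gap_fraction`.

Leading and trailing majority-gap columns (gap fraction > 0.5) are trimmed
before motif testing, so the "C-terminal" doublet is read from real
sequence ends rather than from alignment overhangs contributed by a few
long members. A family is a hit when the final two trimmed columns are
strong (uppercase) consensus spelling GG or CC and both are conserved at
`cons_min` or better, and the family's **median** ungapped member length is
below `max_len` (median, not mean: robust to fusion outliers). The
doublet is required at the final two trimmed columns; allowing a short
C-terminal extension past the doublet (processed modifiers are cleaved
after the GG) would be a reasonable alternative and can be emulated by
trimming the alignment externally.

Defaults: `plurality_min = 0.5`, `cons_min = 0.8`, `max_len = 200` aa,
motifs `{GG, CC}`. The length cutoff is the defining property of the
target families (small β-grasp modifiers); the two conservation thresholds
are this package's own calibration — strict enough that "conserved motif"
is meaningful, loose enough for real families — and are exposed as
parameters. Raising `cons_min` can only remove hits, and raising `max_len`
can only add candidates (monotonicity, property-tested).

## Gene-context analysis

Neighborhoods are the ≤ k genes on each side of an anchor in gene order
(k = 3 by default, matching the classic ±3 window), truncated at linear
replicon ends and wrapped on circular replicons with each gene appearing
at most once. Association records aggregate (anchor cluster, neighbor
cluster) pairs: the genome set is deduplicated (a genome with several
paralogous anchors is one observation — cross-genome recurrence, not
paralogy, is the evidence), while `occurrence_count` keeps the raw total;
the sum of occurrence counts equals the number of assigned neighbors over
all windows (conservation of counts, property-tested). Records are ranked
by number of distinct lineages, then genomes — an association that recurs
in independent lineages is evolutionarily conserved, which is the whole
inferential point of the method. Neighbors without any cluster assignment
are pooled under `UNASSIGNED`.

Operons are maximal same-strand runs with intergenic gaps
`next.start − prev.end − 1 ≤ d_max` (default 100 bp, the common
prokaryotic heuristic); strand switches always split. A flanking gene is
flagged divergent when its 5′ end faces the operon's 5′ end across the
gap (minus-strand gene immediately before a plus-strand operon, and
mirror-image). Fusion detection reports genes with ≥ 2 cluster
assignments, domains ordered by start coordinate, with an overlap flag
when two domains overlap by more than `min_sep` (default 10 aa) residues;
assignments lacking coordinates leave the flag unset with a warning.
Neighborhood windows deliberately cross operon boundaries: the ±k window
is annotation-order based.

## Phyletic patterns

Presence is binary (≥ 1 assignment of the cluster in the genome);
copy number is ignored here because the phyletic arguments the matrix
supports are presence/absence arguments. Genome column order follows the
lineage-map file so reports stay grouped by lineage; cluster rows are
sorted. `absence_report` and `pattern_query` are mutually consistent by
construction: a cluster satisfies an absence constraint set S exactly when
S is contained in its absence list (property-tested).

## Phylogenetics

**Site selection.** Informative positions are parsimony-informative
columns (≥ 2 residue types, each in ≥ 2 sequences) with gap/unknown
fraction ≤ `max_gap_frac` (default 0.5). The criterion is recorded with
the output (a sites TSV of 0-based column indices).

**Model.** JTT with its published equilibrium frequencies (no +F, no rate
heterogeneity; +Γ is out of scope). The rate matrix `Q_ij = S_ij π_j` is
normalised to one expected substitution/site, and `P(t) = expm(Qt)` is
computed by eigendecomposition of the symmetrised matrix
`diag(√π) Q diag(1/√π)` — exact for a reversible model. The matrix
constants were cross-checked against an independent implementation; the
pruning likelihood on a fixed 6-taxon dataset agrees with R/phangorn's
JTT likelihood to 9 decimal places (frozen in the test suite).

**Likelihood.** Felsenstein pruning over compressed site patterns; gaps
and non-standard residues are missing data (all-ones partials), so an
all-gap site has log-likelihood 0. No scaling is used — at the tree sizes
this package targets (≤ ~12 taxa) partial likelihoods stay far from
underflow. Likelihood is invariant under re-rooting of the unrooted
representation (pulley principle, tested to 1e-10).

**Distances and starting tree.** Pairwise distances maximise
`Σ log(π_i P_ij(t))` over shared non-gap columns on `t ∈ [0, 10]`
(bounded Brent); the count matrix is symmetrised so the estimate is
bitwise symmetric in its arguments. The starting topology is
neighbor-joining (scikit-bio) with negative branch lengths clamped —
a fully specified stand-in for the older Fitch–Margoliash distance start,
serving the same role as a reasonable topology for local rearrangement.

**Branch lengths.** Cyclic per-branch univariate optimisation (bounded
Brent on [1e-8, 10], `xatol` 1e-8) with cached inside/outside partial
vectors, so one likelihood evaluation along a branch costs a single
pattern × 20 matrix product; sweeps stop when the total log-likelihood
improves by < 1e-6. Moves are accepted only when they improve, so the
log-likelihood is non-decreasing.

**Tree search.** Nearest-neighbor-interchange hill climbing: both NNI
alternatives of every internal edge are evaluated with full branch-length
re-optimisation, the best strictly improving move is accepted, and the
search repeats to a local optimum. The local-rearrangement neighborhood
is NNI (the minimal local move set); exhaustive enumeration over all
topologies is provided for ≤ ~8 taxa as a cross-check and is used by the
acceptance suite to confirm the NNI search finds the global ML topology
on well-resolved 5-taxon data.

**RELL bootstrap.** Per-site log-likelihoods of a fixed candidate set are
resampled with replacement (multinomial weights, 10,000 replicates by
default); each replicate is awarded to the arg-max candidate, ties split
equally (1/|argmax| each), so supports sum to exactly 100%. The candidate
set for branch supports is the ML tree plus all of its NNI rearrangements
with re-optimised branch lengths; a branch's support is the total support
of candidates containing its bipartition. Replicates resample the
selected site set (the same columns the tree was built from). The RNG is
seeded from configuration for bit-reproducibility; supports are written
as integer-rounded percentages on internal nodes of the output Newick.

**Known bias.** Branch lengths estimated from parsimony-informative
columns only are systematically inflated (constant and singleton sites
carry most of the evidence for short branches). This is inherent to the
informative-positions protocol, which trades unbiased lengths for
signal-dense topology estimation on small families. Where unbiased
lengths matter (e.g. parameter-recovery measurements on simulated data),
`ml_tree` accepts an explicit site set covering all columns; the
acceptance suite measures branch-length recovery that way and topology
recovery both ways.

## Synthetic data

Generators are pure functions of (configuration, seed) and record exact
truth objects. Planting is deterministic by default — an association at
frequency f across n genomes occupies exactly ⌈fn⌉ genomes, a motif at
conservation c exactly round(c·m) members (non-carriers are resampled so
they never end with the motif by chance) — so expected analysis outputs
are exact; a Bernoulli mode exists for distributional tests. Background
gene lengths are uniform on [80, 400] aa so the 200 aa filter has both
sides populated; intergenic gaps are uniform on [10, 200] bp; strands are
fair coin flips; each genome is one linear replicon unless the circular
flag is set. By default every genome is its own lineage (the most
conservative ranking setting); any genome→lineage map can be supplied.
Sequence evolution draws the root from JTT equilibrium and mutates sites
independently along branches via `P(t)`; no indels.

What passing these tests shows: the algorithms compute exactly what they
claim on data matching their model assumptions. What they do not show:
robustness to correlated background (operon structure, shared ancestry of
gene orders, paralog clustering), alignment error, indels,
among-site rate variation, or compositional heterogeneity — all present
in real genomes and alignments.

## Problem sizes and defaults used in validation

The validation and acceptance runs use: 200 random alignments (≤ 20 × 100)
for the consensus oracle; 50 families (20 planted at conservation 0.9, 30
decoys at ≤ 0.5, lengths 80–320 aa) for the motif screen; 1000 random
neighborhood cases; 10 genomes × 200 genes with a 100-cluster background
pool and one association planted at f = 0.8 (20 seeds in Bernoulli mode);
100 random quartets for the likelihood oracle; 10 seeds × 2000 sites for
the 5-taxon exhaustive-search equivalence; and 10 seeds × 1000 sites on a
fixed 8-taxon tree (all internal branches ≥ 0.2) for topology, branch
length and RELL-support recovery, with 10,000 RELL replicates throughout.
Branch-length recovery is summarised as the mean relative error over
branches among seeds that recovered the true topology.

## Limitations

- No rate heterogeneity or empirical-frequency (+F) variants; small
  families only (the search is local; exhaustive checks stop at ~8 taxa).
- Operon prediction is a distance heuristic, not a transcription-unit
  model.
- The motif scan tests the final two trimmed columns only; genuinely
  processed families with post-GG extensions require upstream trimming.
- The arCOG-style importer accepts the tabular dialect described above;
  reproducing published database-wide counts requires the external
  database itself and is outside the test scope.
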