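"""Protein maximum-likelihood phylogenies under JTT with RELL bootstrap.

The tree protocol mirrors the classic MOLPHY-style workflow for small
protein families:

1. select informative alignment positions (parsimony-informative columns
   with bounded gap content),
2. compute pairwise JTT maximum-likelihood distances and build a
   neighbor-joining starting tree,
3. optimise branch lengths and perform local rearrangement (nearest
   neighbor interchange hill-climbing) under the JTT likelihood,
4. attach RELL (resampling of estimated log-likelihoods) bootstrap
   supports: per-site log-likelihoods of a candidate tree set are
   resampled with replacement, each replicate is awarded to the candidate
   with the highest resampled total, and a branch's support is the
   percentage of replicates won by candidates containing its bipartition.

Likelihoods use Felsenstein pruning over the 20 amino-acid states with the
JTT rate matrix normalised to one expected substitution per site; gaps and
non-standard residues are treated as missing data.  Site patterns are
compressed, and per-branch optimisation uses cached inside/outside partial
vectors so each likelihood evaluation along a branch costs a single
20x20 matrix product per site pattern.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import jtt
from .genome_io import ClusterAlignment

BL_MIN = 1e-8
BL_MAX = 10.0

_STANDARD = set(jtt.AMINO_ACIDS)
MISSING_CODE = 20


# ---------------------------------------------------------------------------
# Tree structure


class Node:
    """A node of a (usually unrooted, trifurcating-root) phylogeny."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root representation) with branch lengths."""

    root: Node
    log_likelihood: float | None = None
    per_site_loglik: np.ndarray | None = None

    # -- traversal -----------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def n_branches(self) -> int:
        return len(self.postorder()) - 1

    # -- copy ----------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(n: Node) -> Node:
            m = Node(n.name, n.length)
            for c in n.children:
                m.add(clone(c))
            return m

        return PhyloTree(clone(self.root))

    # -- newick --------------------------------------------------------
    def newick(self, labels: dict[frozenset, str] | None = None) -> str:
        """Newick string; optional internal-node labels keyed by bipartition
        (the leaf set under the node)."""

        def fmt(n: Node) -> str:
            if n.is_leaf():
                body = n.name
            else:
                inner = ",".join(fmt(c) for c in n.children)
                label = ""
                if labels is not None and n.parent is not None:
                    label = labels.get(frozenset(_leafset(n)), "")
                body = f"({inner}){label}"
            if n.length is not None:
                body += f":{n.length:.6f}"
            return body

        return fmt(self.root) + ";"

    # -- topology ------------------------------------------------------
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each normalised to the side that does
        not contain the alphabetically first leaf."""
        all_leaves = set(self.leaf_names())
        ref = min(all_leaves)
        out: set[frozenset] = set()
        for n in self.postorder():
            if n.parent is None or n.is_leaf():
                continue
            side = set(_leafset(n))
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            out.add(frozenset(all_leaves - side if ref in side else side))
        return out

    def same_topology(self, other: "PhyloTree") -> bool:
        return (set(self.leaf_names()) == set(other.leaf_names())
                and self.bipartitions() == other.bipartitions())


def _leafset(n: Node) -> list[str]:
    if n.is_leaf():
        return [n.name]
    out: list[str] = []
    stack = [n]
    while stack:
        m = stack.pop()
        if m.is_leaf():
            out.append(m.name)
        else:
            stack.extend(m.children)
    return out


def parse_newick(newick: str) -> PhyloTree:
    """Parse a Newick string (via scikit-bio) into a PhyloTree."""
    from skbio import TreeNode as SkbioNode

    sk = SkbioNode.read(io.StringIO(newick))

    def convert(s) -> Node:
        n = Node(s.name, None if s.length is None else max(0.0, float(s.length)))
        for c in s.children:
            n.add(convert(c))
        return n

    root = convert(sk)
    root.length = None
    return PhyloTree(root)


def reroot_at(tree: PhyloTree, node: Node) -> PhyloTree:
    """Re-root the unrooted representation at an internal node (in place).

    The unrooted tree is unchanged; only the direction of parent pointers
    along the path to the old root is reversed.  A degree-two old root is
    spliced out.
    """
    if node.parent is None:
        return tree
    path: list[Node] = []
    n: Node | None = node
    while n is not None:
        path.append(n)
        n = n.parent
    old_lengths = [c.length for c in path[:-1]]
    for child, par in zip(path, path[1:]):
        par.children.remove(child)
    for (child, par), length in zip(zip(path, path[1:]), old_lengths):
        child.children.append(par)
        par.parent = child
        par.length = length
    node.parent = None
    node.length = None
    old_root = path[-1]
    if len(old_root.children) == 1:  # suppress degree-2 node
        only = old_root.children[0]
        par = old_root.parent
        only.length = (only.length or 0.0) + (old_root.length or 0.0)
        par.children[par.children.index(old_root)] = only
        only.parent = par
    tree.root = node
    tree.log_likelihood = None
    tree.per_site_loglik = None
    return tree


# ---------------------------------------------------------------------------
# Site selection


@dataclass
class SiteSet:
    cluster_id: str
    selected_columns: list[int]

    def __len__(self) -> int:
        return len(self.selected_columns)


def select_informative_positions(aln: ClusterAlignment,
                                 max_gap_frac: float = 0.5) -> SiteSet:
    """Parsimony-informative columns with bounded gap content.

    A column is selected when its fraction of gaps/non-standard residues is
    <= max_gap_frac and it shows >= 2 distinct residues each present in
    >= 2 sequences.
    """
    n = aln.n_members
    selected: list[int] = []
    for j in range(aln.n_columns):
        counts: dict[str, int] = {}
        n_missing = 0
        for _, seq in aln.sequences:
            ch = seq[j]
            if ch in _STANDARD:
                counts[ch] = counts.get(ch, 0) + 1
            else:
                n_missing += 1
        if n_missing / n > max_gap_frac:
            continue
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            selected.append(j)
    if not selected:
        raise ValueError(
            "no informative positions selected; relax max_gap_frac or provide "
            "a more variable alignment")
    return SiteSet(aln.cluster_id, selected)


# ---------------------------------------------------------------------------
# Pairwise ML distances and neighbor joining


def jtt_distance(seq1: str, seq2: str) -> float:
    """Pairwise ML distance (substitutions/site) under the JTT model.

    Maximises sum over shared non-gap columns of log(pi_i * P_ij(t)) on
    t in [0, 10].  Symmetric by reversibility of the model.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    pairs = [(a, b) for a, b in zip(seq1, seq2)
             if a in _STANDARD and b in _STANDARD]
    if not pairs:
        raise ValueError("no shared non-gap columns")
    if all(a == b for a, b in pairs):
        return 0.0
    counts = np.zeros((20, 20))
    for a, b in pairs:
        counts[jtt.AA_INDEX[a], jtt.AA_INDEX[b]] += 1
    # pi_i P_ij(t) is symmetric under reversibility, so folding the counts
    # makes the objective bitwise identical for either argument order
    counts = (counts + counts.T) / 2.0
    log_pi = np.log(jtt.JTT_FREQUENCIES)

    def neg_loglik(t: float) -> float:
        with np.errstate(divide="ignore"):
            lp = np.log(jtt.transition_matrix(t))
        return -float((counts * (log_pi[:, None] + lp)).sum())

    res = minimize_scalar(neg_loglik, bounds=(BL_MIN, BL_MAX), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def distance_matrix(aln: ClusterAlignment) -> tuple[np.ndarray, list[str]]:
    """All pairwise JTT distances; returns (matrix, member ids)."""
    ids = [m for m, _ in aln.sequences]
    seqs = [s for _, s in aln.sequences]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jtt_distance(seqs[i], seqs[j])
    return d, ids


def nj_tree(dist: np.ndarray, ids: list[str]) -> PhyloTree:
    """Neighbor-joining starting tree (scikit-bio agglomeration).

    Negative branch lengths are clamped to zero.  For two taxa the tree is
    a single edge of length d12 (one taxon becomes the root).
    """
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        root = Node(ids[0])
        root.add(Node(ids[1], float(dist[0, 1])))
        return PhyloTree(root)
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    sk = skbio_nj(DistanceMatrix(dist, ids))
    tree = parse_newick(str(sk))
    for node in tree.postorder():
        if node.parent is not None:
            node.length = max(BL_MIN, node.length if node.length is not None else BL_MIN)
    return tree


# ---------------------------------------------------------------------------
# Likelihood engine


class LikelihoodEngine:
    """Pattern-compressed Felsenstein pruning for one alignment + site set."""

    def __init__(self, aln: ClusterAlignment, siteset: SiteSet):
        self.names = [m for m, _ in aln.sequences]
        cols = siteset.selected_columns
        codes = np.full((len(self.names), len(cols)), MISSING_CODE, dtype=np.int8)
        for i, (_, seq) in enumerate(aln.sequences):
            for k, j in enumerate(cols):
                codes[i, k] = jtt.AA_INDEX.get(seq[j], MISSING_CODE)
        patterns, inverse = np.unique(codes, axis=1, return_inverse=True)
        self.pattern_index = inverse
        self.weights = np.bincount(inverse, minlength=patterns.shape[1]).astype(float)
        self.n_sites = len(cols)
        eye = np.vstack([np.eye(20), np.ones(20)])
        self.leaf_partials = {
            name: eye[patterns[i]] for i, name in enumerate(self.names)
        }
        self.pi = jtt.JTT_FREQUENCIES

    # -- partials ------------------------------------------------------
    def _check(self, tree: PhyloTree) -> None:
        names = [n.name for n in tree.postorder() if n.name is not None]
        if sorted(names) != sorted(self.names):
            raise ValueError("tree taxa do not match alignment members")

    def _down(self, node: Node) -> np.ndarray:
        """Inside partial at ``node``: P(data below | state at node)."""
        if node.name is not None and not node.children:
            return self.leaf_partials[node.name]
        partial = None
        for c in node.children:
            m = self._down(c) @ jtt.transition_matrix(c.length).T
            partial = m if partial is None else partial * m
        if node.name is not None:  # root taxon of a 2-leaf tree
            partial = partial * self.leaf_partials[node.name]
        return partial

    def per_pattern_loglik(self, tree: PhyloTree) -> np.ndarray:
        self._check(tree)
        lik = self._down(tree.root) @ self.pi
        return np.log(lik)

    def loglik(self, tree: PhyloTree) -> tuple[float, np.ndarray]:
        """(total log-likelihood, per-site vector in selected-column order)."""
        per_pattern = self.per_pattern_loglik(tree)
        per_site = per_pattern[self.pattern_index]
        return float(per_pattern @ self.weights), per_site

    # -- branch-length optimisation -------------------------------------
    def _edge_vectors(self, tree: PhyloTree, node: Node) -> tuple[np.ndarray, np.ndarray]:
        """(outside partial at parent, inside partial at node) for the edge
        above ``node``; both are functions of state, per pattern."""
        down: dict[int, np.ndarray] = {}

        def walk(n: Node) -> np.ndarray:
            if n.name is not None and not n.children:
                d = self.leaf_partials[n.name]
            else:
                d = None
                for c in n.children:
                    m = walk(c) @ jtt.transition_matrix(c.length).T
                    d = m if d is None else d * m
                if n.name is not None:
                    d = d * self.leaf_partials[n.name]
            down[id(n)] = d
            return d

        walk(tree.root)

        path: list[Node] = []
        n: Node | None = node
        while n is not None:
            path.append(n)
            n = n.parent
        path.reverse()  # root ... node

        # outside partial H at each node of the path (function of its state)
        h = np.broadcast_to(self.pi, down[id(tree.root)].shape).copy()
        if tree.root.name is not None:
            h = h * self.leaf_partials[tree.root.name]
        for par, child in zip(path, path[1:]):
            g = h.copy()
            for s in par.children:
                if s is not child:
                    g = g * (down[id(s)] @ jtt.transition_matrix(s.length).T)
            if par is not path[0] and par.name is not None:
                g = g * self.leaf_partials[par.name]
            if child is node:
                return g, down[id(node)]
            h = g @ jtt.transition_matrix(child.length)
        raise AssertionError("unreachable")

    def optimize_branch_lengths(self, tree: PhyloTree, tol: float = 1e-6,
                                max_sweeps: int = 30) -> PhyloTree:
        """Cyclic per-branch ML optimisation; log-likelihood never decreases."""
        self._check(tree)
        current, _ = self.loglik(tree)
        for _ in range(max_sweeps):
            before = current
            for node in tree.postorder():
                if node.parent is None:
                    continue
                g, d = self._edge_vectors(tree, node)

                def neg(t: float) -> float:
                    lik = ((d @ jtt.transition_matrix(t).T) * g).sum(axis=1)
                    return -float(np.log(lik) @ self.weights)

                res = minimize_scalar(neg, bounds=(BL_MIN, BL_MAX),
                                      method="bounded", options={"xatol": 1e-8})
                if -res.fun > current:
                    node.length = float(res.x)
                    current = -res.fun
            if current - before < tol:
                break
        tree.log_likelihood, tree.per_site_loglik = self.loglik(tree)
        return tree


def site_loglik(tree: PhyloTree, aln: ClusterAlignment,
                siteset: SiteSet) -> np.ndarray:
    """Per-site log-likelihood vector over the selected columns."""
    engine = LikelihoodEngine(aln, siteset)
    total, per_site = engine.loglik(tree)
    tree.log_likelihood = total
    tree.per_site_loglik = per_site
    return per_site


def optimize_branch_lengths(tree: PhyloTree, aln: ClusterAlignment,
                            siteset: SiteSet, tol: float = 1e-6) -> PhyloTree:
    return LikelihoodEngine(aln, siteset).optimize_branch_lengths(tree, tol=tol)


# ---------------------------------------------------------------------------
# NNI search


def nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All nearest-neighbor-interchange rearrangements of an unrooted tree.

    Two alternatives per internal edge; moved subtrees keep their branch
    lengths (re-optimise afterwards).
    """
    order = tree.postorder()
    internal_edges = [i for i, n in enumerate(order)
                      if n.parent is not None and n.children]
    out: list[PhyloTree] = []
    for ei in internal_edges:
        for alt in (0, 1):
            t2 = tree.copy()
            nodes = t2.postorder()
            c = nodes[ei]
            reroot_at(t2, c.parent)
            p = t2.root
            others = [ch for ch in p.children if ch is not c]
            a = others[alt]
            y = c.children[-1]
            c.children[c.children.index(y)] = a
            a.parent = c
            p.children[p.children.index(a)] = y
            y.parent = p
            out.append(t2)
    return out


def nni_search(start_tree: PhyloTree, aln: ClusterAlignment, siteset: SiteSet,
               tol: float = 1e-6) -> PhyloTree:
    """Hill-climb over NNI rearrangements to a local likelihood optimum.

    Each candidate is evaluated with full branch-length re-optimisation;
    the best strictly improving move is accepted and the search repeats.
    The final log-likelihood is never below the starting one.
    """
    engine = LikelihoodEngine(aln, siteset)
    current = engine.optimize_branch_lengths(start_tree.copy())
    while True:
        best: PhyloTree | None = None
        for neighbor in nni_neighbors(current):
            cand = engine.optimize_branch_lengths(neighbor)
            if best is None or cand.log_likelihood > best.log_likelihood:
                best = cand
        if best is not None and best.log_likelihood > current.log_likelihood + tol:
            current = best
        else:
            return current


def enumerate_topologies(taxa: list[str],
                         branch_length: float = 0.1) -> list[PhyloTree]:
    """All distinct unrooted binary topologies over the given taxa.

    Built by sequential leaf addition on every edge; (2n-5)!! trees.
    Intended for exhaustive ML at small n (tests and cross-checks).
    """
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    base = PhyloTree(Node())
    for t in taxa[:3]:
        base.root.add(Node(t, branch_length))
    trees = [base]
    for taxon in taxa[3:]:
        grown: list[PhyloTree] = []
        for tree in trees:
            n_edges = tree.n_branches()
            for ei in range(n_edges):
                t2 = tree.copy()
                target = [n for n in t2.postorder() if n.parent is not None][ei]
                par = target.parent
                mid = Node(None, branch_length)
                par.children[par.children.index(target)] = mid
                mid.parent = par
                mid.add(target)
                mid.add(Node(taxon, branch_length))
                grown.append(t2)
        trees = grown
    return trees


# ---------------------------------------------------------------------------
# RELL bootstrap


@dataclass
class RellResult:
    candidate_support: np.ndarray            # percent, per candidate
    branch_support: dict[frozenset, float] = field(default_factory=dict)
    n_replicates: int = 0


def rell_bootstrap(candidate_trees: list[PhyloTree] | None,
                   per_site_logliks: list[np.ndarray] | np.ndarray,
                   n_replicates: int = 10000,
                   seed: int | np.random.Generator = 0) -> RellResult:
    """RELL bootstrap over a fixed candidate tree set.

    Site indices are resampled with replacement; each replicate is awarded
    to the candidate with the highest resampled log-likelihood total (ties
    split equally).  When candidate trees are given, a bipartition's branch
    support is the total support of candidates containing it.
    """
    logliks = np.atleast_2d(np.asarray(per_site_logliks, dtype=float))
    n_cand, n_sites = logliks.shape
    if n_sites == 0:
        raise ValueError("empty site set")
    if n_cand == 0:
        raise ValueError("need at least one candidate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wins = np.zeros(n_cand)
    p = np.full(n_sites, 1.0 / n_sites)
    done = 0
    while done < n_replicates:
        chunk = min(2000, n_replicates - done)
        counts = rng.multinomial(n_sites, p, size=chunk).astype(float)
        totals = counts @ logliks.T
        best = totals.max(axis=1, keepdims=True)
        ties = np.abs(totals - best) <= 1e-9
        wins += (ties / ties.sum(axis=1, keepdims=True)).sum(axis=0)
        done += chunk
    support = wins / n_replicates * 100.0

    branch: dict[frozenset, float] = {}
    if candidate_trees is not None:
        for tree, s in zip(candidate_trees, support):
            for bp in tree.bipartitions():
                branch[bp] = branch.get(bp, 0.0) + s
    return RellResult(support, branch, n_replicates)


# ---------------------------------------------------------------------------
# Full protocol


@dataclass
class SupportedTree:
    tree: PhyloTree
    branch_support: dict[frozenset, float]
    siteset: SiteSet
    candidate_support: np.ndarray

    def newick(self) -> str:
        labels = {bp: str(int(round(s))) for bp, s in self.branch_support.items()}
        all_leaves = set(self.tree.leaf_names())
        ref = min(all_leaves)
        keyed: dict[frozenset, str] = {}
        for n in self.tree.postorder():
            if n.parent is None or n.is_leaf():
                continue
            side = frozenset(_leafset(n))
            norm = frozenset(all_leaves - side) if ref in side else side
            if norm in labels:
                keyed[side] = labels[norm]
        return self.tree.newick(labels=keyed)


def ml_tree(aln: ClusterAlignment,
            max_gap_frac: float = 0.5,
            n_replicates: int = 10000,
            seed: int | np.random.Generator = 0,
            siteset: SiteSet | None = None) -> SupportedTree:
    """Run the full protocol: site selection, NJ start, NNI ML search, RELL.

    By default the analysis runs on the informative-position site set
    (pass an explicit ``siteset`` to override, e.g. all columns when
    unbiased branch lengths matter more than protocol fidelity).  The RELL
    candidate set is the maximum-likelihood tree plus all of its NNI
    rearrangements (each with re-optimised branch lengths), so branch
    supports measure how often local alternatives beat the ML resolution.
    """
    if siteset is None:
        siteset = select_informative_positions(aln, max_gap_frac)
    sub = ClusterAlignment(aln.cluster_id, [
        (m, "".join(s[j] for j in siteset.selected_columns))
        for m, s in aln.sequences
    ])
    dist, ids = distance_matrix(sub)
    start = nj_tree(dist, ids)
    best = nni_search(start, aln, siteset)
    engine = LikelihoodEngine(aln, siteset)
    candidates = [best]
    for neighbor in nni_neighbors(best):
        candidates.append(engine.optimize_branch_lengths(neighbor))
    logliks = np.vstack([c.per_site_loglik for c in candidates])
    rell = rell_bootstrap(candidates, logliks, n_replicates, seed)
    return SupportedTree(best, rell.branch_support, siteset, rell.candidate_support)
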