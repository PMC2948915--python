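"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or elementary
counting, sharing no logic with the implementation paths it checks
(only the JTT transition-matrix primitive is shared, as the model
definition itself).
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from ublcontext import jtt
from ublcontext.phylo import PhyloTree


def consensus_columns(rows: list[str], plurality_min: float):
    """Per-column (consensus, conservation, gap_fraction) by direct counting."""
    n = len(rows)
    out = []
    for j in range(len(rows[0])):
        col = [r[j] for r in rows]
        counts = Counter(c for c in col if c != "-")
        gap_fraction = col.count("-") / n
        if not counts:
            out.append(("-", 0.0, gap_fraction))
            continue
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        freq = counts[best] / n
        if freq >= plurality_min:
            cons = best.upper()
        elif gap_fraction > 0.5:
            cons = "-"
        else:
            cons = best.lower()
        out.append((cons, freq, gap_fraction))
    return out


def neighborhood_indices(n: int, anchor: int, k: int, circular: bool):
    """(upstream, downstream) index lists by direct index arithmetic."""
    if circular:
        used = {anchor}
        up, down = [], []
        for s in range(1, k + 1):
            i = (anchor - s) % n
            if i in used:
                break
            used.add(i)
            up.append(i)
        for s in range(1, k + 1):
            i = (anchor + s) % n
            if i in used:
                break
            used.add(i)
            down.append(i)
        return up, down
    up = [i for i in range(anchor - 1, anchor - k - 1, -1) if i >= 0]
    down = [i for i in range(anchor + 1, anchor + k + 1) if i < n]
    return up, down


def site_loglik_enumeration(tree: PhyloTree, leaf_states: dict[str, int | None]) -> float:
    """Log-likelihood of one site by summation over all internal-node states.

    ``leaf_states`` maps leaf name to an amino-acid code, or None for a gap
    (marginalised leaf).
    """
    nodes = tree.postorder()
    internals = [n for n in nodes if n.children]
    probs = {id(n): jtt.transition_matrix(n.length) for n in nodes if n.parent is not None}
    total = 0.0
    for assign in itertools.product(range(20), repeat=len(internals)):
        state = dict(zip((id(n) for n in internals), assign))
        p = jtt.JTT_FREQUENCIES[state[id(tree.root)]]
        for n in nodes:
            if n.parent is None:
                continue
            if not n.children:
                s = leaf_states[n.name]
                if s is None:
                    continue  # marginalised: sum over its states is 1
            else:
                s = state[id(n)]
            p *= probs[id(n)][state[id(n.parent)], s]
        total += p
    return float(np.log(total))


def jtt_distance_grid(seq1: str, seq2: str, dt: float = 1e-4, t_max: float = 2.0) -> float:
    """Pairwise JTT ML distance by 1-D grid search of the same objective."""
    idx = [(jtt.AA_INDEX[a], jtt.AA_INDEX[b]) for a, b in zip(seq1, seq2)
           if a in jtt.AA_INDEX and b in jtt.AA_INDEX]
    log_pi = np.log(jtt.JTT_FREQUENCIES)
    best_t, best_ll = 0.0, -np.inf
    t = dt
    while t <= t_max:
        lp = np.log(jtt.transition_matrix(t))
        ll = sum(log_pi[i] + lp[i, j] for i, j in idx)
        if ll > best_ll:
            best_t, best_ll = t, ll
        t += dt
    return best_t


def edge_lengths_by_bipartition(tree: PhyloTree) -> dict[frozenset, float]:
    """Branch lengths keyed by the (normalised) leaf-set bipartition of each edge."""
    all_leaves = set(tree.leaf_names())
    ref = min(all_leaves)
    out: dict[frozenset, float] = {}

    def leafset(n):
        if not n.children:
            return {n.name}
        s = set()
        for c in n.children:
            s |= leafset(c)
        if n.name is not None:
            s.add(n.name)
        return s

    for n in tree.postorder():
        if n.parent is None:
            continue
        side = leafset(n)
        key = frozenset(all_leaves - side) if ref in side else frozenset(side)
        out[key] = out.get(key, 0.0) + (n.length or 0.0)
    return out
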