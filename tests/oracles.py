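"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity from first principles (path enumeration,
exhaustive enumeration, naive loops) without calling the implementation it
checks; tree-based oracles parse newick with dendropy rather than the
package's tree stack.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np


# ---------------------------------------------------------------------------
# Tree metrics by root-to-tip path enumeration (dendropy)
# ---------------------------------------------------------------------------


def _edges_to_root(tree: dendropy.Tree) -> dict[str, list]:
    """Per tip label: the list of edges on the path tip → root."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append(node.edge)
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    return paths


def faith_pd_bruteforce(newick: str, present: set[str]) -> float:
    """Total length of the union of root-to-tip paths of present tips."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    paths = _edges_to_root(tree)
    seen = set()
    total = 0.0
    for tip in present:
        for edge in paths[tip]:
            if id(edge) not in seen:
                seen.add(id(edge))
                total += edge.length or 0.0
    return total


def unifrac_bruteforce(newick: str, set_a: set[str], set_b: set[str]) -> float:
    """Unweighted UniFrac = unique / total observed branch length."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    paths = _edges_to_root(tree)

    def edge_union(tips: set[str]) -> dict[int, float]:
        out = {}
        for tip in tips:
            for edge in paths[tip]:
                out[id(edge)] = edge.length or 0.0
        return out

    ea, eb = edge_union(set_a), edge_union(set_b)
    union = {**ea, **eb}
    shared = set(ea) & set(eb)
    total = sum(union.values())
    unique = sum(l for eid, l in union.items() if eid not in shared)
    if total == 0:
        return 0.0
    return unique / total


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------


def fisher_greater_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher p as a hypergeometric tail sum.

    Margins: row1 = a+b draws, column1 = a+c successes, N = a+b+c+d.
    """
    n = a + b + c + d
    k_draws = a + b
    k_success = a + c
    denom = math.comb(n, k_draws)
    p = 0.0
    for x in range(a, min(k_draws, k_success) + 1):
        if k_draws - x > n - k_success:
            continue
        p += math.comb(k_success, x) * math.comb(n - k_success, k_draws - x) / denom
    return min(p, 1.0)


def bh_bruteforce(pvalues) -> list[float]:
    """Naive step-up BH with explicit loops."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top, 1.0)
        adjusted[i] = val
        prev = val
    return adjusted


def wilcoxon_bruteforce(x, y) -> float:
    """Two-sided exact rank-sum p by full enumeration of assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)
    # midranks
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    w_obs = sum(ranks[:n])
    expected = n * (len(pooled) + 1) / 2
    dev = abs(w_obs - expected)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        w = sum(ranks[i] for i in combo)
        total += 1
        if abs(w - expected) >= dev - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Reaction abundance
# ---------------------------------------------------------------------------


def reaction_abundance_bruteforce(
    counts: np.ndarray,
    mapped: list[int],
    e_matrix: np.ndarray,
) -> np.ndarray:
    """Double-loop evaluation of a_r(i) over mapped ASVs.

    ``counts``: samples × ASVs; ``mapped``: column indices of mapped ASVs;
    ``e_matrix``: len(mapped) × reactions.
    """
    n_samples = counts.shape[0]
    n_reactions = e_matrix.shape[1]
    out = np.zeros((n_samples, n_reactions))
    for i in range(n_samples):
        denom = sum(counts[i, j] for j in mapped)
        for r in range(n_reactions):
            num = 0.0
            for jj, j in enumerate(mapped):
                num += counts[i, j] * e_matrix[jj, r]
            out[i, r] = num / denom
    return out
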