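"""Independent oracles used by the test suite.

Everything here is deliberately naive — memoized recursions over explicit
alignment moves, path-length distances on explicitly built trees, clade
enumeration — so the oracles share no code path with the package.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from skbio import TreeNode


# ---------------------------------------------------------------------------
# Alignment score oracles (affine gaps: a gap of length k costs open + k*ext)

def global_score(a: str, b: str, sub, gap_open: float, gap_ext: float) -> float:
    """Best global alignment score by recursion over alignment moves."""

    la, lb = len(a), len(b)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == la and j == lb:
            return 0.0
        options = []
        if i < la and j < lb:
            options.append(sub(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < la:
            cost = gap_ext if prev == "D" else gap_open + gap_ext
            options.append(-cost + best(i + 1, j, "D"))
        if j < lb:
            cost = gap_ext if prev == "I" else gap_open + gap_ext
            options.append(-cost + best(i, j + 1, "I"))
        return max(options)

    result = best(0, 0, "M")
    best.cache_clear()
    return result


def local_score(a: str, b: str, sub, gap_open: float, gap_ext: float) -> float:
    """Best local score: max over all substring pairs of their global
    score, floored at the empty alignment (0)."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    s = global_score(a[i0:i1], b[j0:j1], sub,
                                     gap_open, gap_ext)
                    best = max(best, s)
    return best


# ---------------------------------------------------------------------------
# Random trees, additive matrices, clades

def random_binary_tree(rng: np.random.Generator, n_leaves: int,
                       blen_range=(0.05, 1.0)) -> TreeNode:
    """Random rooted binary tree over leaves L01..Lnn with random branch
    lengths, built by repeated random joins."""
    lo, hi = blen_range
    nodes = [TreeNode(name=f"L{k:02d}", length=float(rng.uniform(lo, hi)))
             for k in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]],
                          length=float(rng.uniform(lo, hi)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    return root


def path_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length (additive) distances."""
    tips = sorted(tree.tips(), key=lambda t: t.name)
    labels = [t.name for t in tips]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tips[i].distance(tips[j])
    return labels, d


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial unrooted splits, each canonicalized to its smaller
    (then lexicographically smaller) side."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        if (len(side), sorted(side)) <= (len(other), sorted(other)):
            splits.add(side)
        else:
            splits.add(other)
    return splits


def brute_force_smallest_clade(tree: TreeNode, ids: set[str]) -> frozenset[str]:
    """Smallest clade (by leaf count) among all rooted clades containing
    every id; enumeration over every node of the tree."""
    best = None
    for node in tree.postorder(include_self=True):
        leaves = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        if ids <= leaves and (best is None or len(leaves) < len(best)):
            best = leaves
    return best
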