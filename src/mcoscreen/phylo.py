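"""Criterion 4 — distance-based phylogeny and the same-clade test.

Pairwise Poisson-corrected distances from global alignments feed a
Saitou-Nei neighbor-joining tree over the reference set plus surviving
candidates.  The tree is rooted on the edge separating the OUTGROUP
leaves, and a candidate satisfies the clade criterion when the smallest
clade containing it and its assigned known Mn-oxidizing gene contains no
NEGATIVE reference.  Neighbor-joining is implemented here with fully
deterministic tie-breaking; trees are skbio TreeNode objects, so Newick
round-trips, LCA queries and rooting use scikit-bio.
"""

from __future__ import annotations

import io
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .align import ScoringScheme, global_align
from .seq_io import ProteinRecord

#: distance assigned when sequences share no identical aligned residue (p=1)
SATURATION_CAP = 10.0


def pairwise_distance(a: ProteinRecord, b: ProteinRecord,
                      scheme: ScoringScheme,
                      cap: float = SATURATION_CAP) -> float:
    """Poisson-corrected distance ``-ln(1 - p)`` from the global alignment.

    ``p`` is the fraction of non-identical residue-residue columns; gap
    columns are excluded from the denominator.  ``p = 1`` (or an
    alignment with no residue-residue column) maps to ``cap``.

    Operands are ordered canonically before aligning: among co-optimal
    alignments the returned one depends on operand order, so the match
    count (hence ``p``) would otherwise not be exactly symmetric.
    """
    if (b.residues, b.id) < (a.residues, a.id):
        a, b = b, a
    aln = global_align(a, b, scheme)
    if aln.n_residue_columns == 0:
        return cap
    p = 1.0 - aln.n_matches / aln.n_residue_columns
    if p >= 1.0:
        return cap
    return min(-math.log(1.0 - p), cap)


def distance_matrix(records: Sequence[ProteinRecord],
                    scheme: ScoringScheme,
                    cap: float = SATURATION_CAP) -> DistanceMatrix:
    """Symmetric Poisson-corrected distance matrix over ``records``."""
    ids = [r.id for r in records]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(records[i], records[j],
                                                  scheme, cap)
    return DistanceMatrix(d, ids=ids)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing Q is joined; ties break on the lexicographically
    smallest (sorted) pair of node keys, where an internal node's key is
    the smallest leaf label beneath it.  Negative branch lengths are
    clamped to 0 with the deficit shifted onto the sibling branch.  The
    returned tree is unrooted by convention: its root trifurcates.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate labels in distance matrix")

    # working state: node key -> TreeNode, and dense distances keyed by key
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    dist: dict[tuple[str, str], float] = {}
    for i in ids:
        for j in ids:
            if i < j:
                dist[(i, j)] = float(dm[i, j])

    def d(x: str, y: str) -> float:
        return 0.0 if x == y else dist[(min(x, y), max(x, y))]

    active = sorted(nodes)
    while len(active) > 3:
        n = len(active)
        r = {i: sum(d(i, k) for k in active) for i in active}
        best_pair = None
        best_q = math.inf
        for ii in range(n):
            for jj in range(ii + 1, n):
                i, j = active[ii], active[jj]
                q = (n - 2) * d(i, j) - r[i] - r[j]
                if q < best_q - 1e-12 or (
                        abs(q - best_q) <= 1e-12
                        and best_pair is not None and (i, j) < best_pair):
                    best_q = q
                    best_pair = (i, j)
        i, j = best_pair
        dij = d(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new_key = min(i, j)
        parent = TreeNode(children=[child_i, child_j])
        # update distances to the new node before dropping i and j
        for k in active:
            if k in (i, j):
                continue
            duk = max(0.0, (d(i, k) + d(j, k) - dij) / 2.0)
            dist[(min(new_key, k), max(new_key, k))] = duk
        active = sorted(set(active) - {i, j} | {new_key})
        del nodes[i], nodes[j]
        nodes[new_key] = parent

    # resolve the last three nodes around a trifurcating root
    x, y, z = active
    lx = max(0.0, (d(x, y) + d(x, z) - d(y, z)) / 2.0)
    ly = max(0.0, (d(x, y) + d(y, z) - d(x, z)) / 2.0)
    lz = max(0.0, (d(x, z) + d(y, z) - d(x, y)) / 2.0)
    for key, length in ((x, lx), (y, ly), (z, lz)):
        nodes[key].length = length
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    return root


# ---------------------------------------------------------------------------
# Rooting and clades

def _tip_names(node: TreeNode) -> frozenset[str]:
    if node.is_tip():
        return frozenset([node.name])
    return frozenset(t.name for t in node.tips())


def root_at_outgroup(tree: TreeNode, outgroup_ids: Iterable[str]) -> TreeNode:
    """Root on the edge separating the outgroup, at the edge midpoint.

    The outgroup must form one side of an edge of the unrooted tree
    (i.e. be monophyletic); otherwise a hard error lists the intruding
    leaves of the smallest clade spanning the outgroup.
    """
    outgroup = frozenset(outgroup_ids)
    if not outgroup:
        raise ValueError("outgroup_ids must be non-empty")
    tips = _tip_names(tree)
    unknown = outgroup - tips
    if unknown:
        raise ValueError(f"outgroup ids not in tree: {sorted(unknown)}")
    if outgroup == tips:
        raise ValueError("outgroup cannot contain every leaf")

    target = None
    for node in tree.postorder(include_self=False):
        below = _tip_names(node)
        if below == outgroup or below == tips - outgroup:
            target = node
            break
    if target is None:
        spanning = _tip_names(tree.lca(sorted(outgroup)))
        intruders = sorted(spanning - outgroup)
        raise ValueError(
            f"outgroup {sorted(outgroup)} is not monophyletic; the smallest "
            f"spanning clade also contains {intruders}")

    half = (target.length or 0.0) / 2.0
    rooted = tree.root_at(target, above=half, branch_attrs=[])
    return rooted


def smallest_clade(tree: TreeNode, ids: Iterable[str]) -> frozenset[str]:
    """Leaf set of the most recent common ancestor of ``ids``."""
    ids = sorted(set(ids))
    if not ids:
        raise ValueError("ids must be non-empty")
    tips = _tip_names(tree)
    unknown = [i for i in ids if i not in tips]
    if unknown:
        raise ValueError(f"unknown leaf ids: {unknown}")
    if len(ids) == 1:
        return frozenset(ids)
    return _tip_names(tree.lca(ids))


def criterion4(candidate_id: str, assigned_ref_id: str, tree: TreeNode,
               negative_ids: Iterable[str]) -> tuple[bool, frozenset[str]]:
    """Same-clade test with the assigned known Mn-oxidizing gene.

    Passes iff the smallest clade containing the candidate and its
    assigned reference contains no NEGATIVE reference leaf.
    """
    clade = smallest_clade(tree, [candidate_id, assigned_ref_id])
    negatives = frozenset(negative_ids)
    return clade.isdisjoint(negatives), clade


# ---------------------------------------------------------------------------
# Newick I/O (fixed 6-decimal branch lengths for byte-stable output)

def _newick_str(node: TreeNode) -> str:
    if node.is_tip():
        label = node.name or ""
        label = label.replace(" ", "_")
    else:
        label = ""
        inner = ",".join(_newick_str(c) for c in node.children)
        label = f"({inner})" + (node.name or "")
    if node.length is not None:
        label += f":{node.length:.6f}"
    return label


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(_newick_str(tree) + ";\n")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
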