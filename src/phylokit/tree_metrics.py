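"""Tree summary statistics: counts, branch-length summaries, cherries,
Colless and Sackin imbalance, patristic distances."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .distances import DistanceMatrix
from .tree import Node, PhyloError, Tree

__all__ = [
    "TreeStats",
    "tree_stats",
    "count_cherries",
    "colless",
    "sackin",
    "patristic_matrix",
]


@dataclass
class TreeStats:
    n_tips: int
    n_internal_nodes: int
    n_edges: int
    sum_length: Optional[float]
    mean_length: Optional[float]
    min_length: Optional[float]
    max_length: Optional[float]
    mean_support: Optional[float]
    n_cherries: int
    colless: Optional[int]
    sackin: Optional[int]
    rooted: bool


def tree_stats(tree: Tree) -> TreeStats:
    """All summary fields; imbalance indices are absent for unrooted trees."""
    nodes = list(tree.preorder())
    tips = [n for n in nodes if n.is_tip]
    lengths = [n.length for n in nodes if n is not tree.root and n.length is not None]
    supports = [n.support for n in nodes if n.support is not None]
    rooted = tree.is_rooted
    col = sac = None
    if rooted:
        try:
            col = colless(tree)
        except PhyloError:
            col = None
        sac = sackin(tree)
    return TreeStats(
        n_tips=len(tips),
        n_internal_nodes=len(nodes) - len(tips),
        n_edges=len(nodes) - 1,
        sum_length=sum(lengths) if lengths else None,
        mean_length=sum(lengths) / len(lengths) if lengths else None,
        min_length=min(lengths) if lengths else None,
        max_length=max(lengths) if lengths else None,
        mean_support=sum(supports) / len(supports) if supports else None,
        n_cherries=count_cherries(tree) if len(tips) >= 2 else 0,
        colless=col,
        sackin=sac,
        rooted=rooted,
    )


def count_cherries(tree: Tree) -> int:
    """Internal nodes adjacent (unrooted sense) to exactly two tips.

    A bifurcating root is suppressed before counting so the result is
    invariant under rerooting; trees of two or three tips, whose unrooted
    versions degenerate, count as a single cherry.
    """
    n = tree.n_tips
    if n < 2:
        return 0
    if n <= 3:
        return 1
    # adjacency in the unrooted sense: children plus parent, with a
    # bifurcating root suppressed (its two children become neighbors)
    work = tree.copy()
    if len(work.root.children) == 2:
        a, b = work.root.children
        extra_adj = {id(a): [b], id(b): [a]}
        skip = {id(work.root)}
    else:
        extra_adj = {}
        skip = set()
    count = 0
    for node in work.preorder():
        if node.is_tip or id(node) in skip:
            continue
        neighbors = list(node.children)
        if node.parent is not None and id(node.parent) not in skip:
            neighbors.append(node.parent)
        neighbors.extend(extra_adj.get(id(node), []))
        if sum(1 for x in neighbors if x.is_tip) == 2:
            count += 1
    return count


def _subtree_tip_counts(tree: Tree) -> dict:
    counts: dict[int, int] = {}
    for node in tree.postorder():
        counts[id(node)] = (
            1 if node.is_tip else sum(counts[id(c)] for c in node.children)
        )
    return counts


def colless(tree: Tree) -> int:
    """Sum over internal nodes of |left - right| subtree tip counts."""
    if not tree.is_rooted:
        raise PhyloError("Colless index requires a rooted tree")
    counts = _subtree_tip_counts(tree)
    total = 0
    for node in tree.preorder():
        if node.is_tip:
            continue
        if len(node.children) != 2:
            raise PhyloError("Colless index requires a strictly binary tree")
        left, right = node.children
        total += abs(counts[id(left)] - counts[id(right)])
    return total


def sackin(tree: Tree) -> int:
    """Sum over tips of the root-to-tip depth in edges."""
    if not tree.is_rooted:
        raise PhyloError("Sackin index requires a rooted tree")
    total = 0
    stack = [(tree.root, 0)]
    while stack:
        node, depth = stack.pop()
        if node.is_tip:
            total += depth
        for child in node.children:
            stack.append((child, depth + 1))
    return total


def patristic_matrix(tree: Tree) -> DistanceMatrix:
    """Tip-by-tip path-length (patristic) distance matrix."""
    if not tree.has_all_lengths():
        raise PhyloError("patristic distances require all branch lengths")
    names = tree.tip_names()
    index = {name: i for i, name in enumerate(names)}
    n = len(names)
    mat = np.zeros((n, n))
    # at each internal node, cross-combine the tip distances of its child
    # subtrees; each tip pair meets exactly once, at its MRCA
    below: dict[int, list] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = [(index[node.label], 0.0)]
            continue
        child_lists = []
        for child in node.children:
            lst = [(i, d + (child.length or 0.0)) for i, d in below.pop(id(child))]
            child_lists.append(lst)
        for a in range(len(child_lists)):
            for b in range(a + 1, len(child_lists)):
                for i, di in child_lists[a]:
                    for j, dj in child_lists[b]:
                        mat[i, j] = mat[j, i] = di + dj
        below[id(node)] = [pair for lst in child_lists for pair in lst]
    return DistanceMatrix(names, mat)
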