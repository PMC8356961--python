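"""Tree modification and generation: pruning, rerooting, collapsing,
renaming, polytomy resolution and random tree generation.

Rerooting is implemented as a generic "place the root on an edge"
operation that reverses the parent pointers on the path to the old root
and suppresses the resulting degree-2 node; it preserves the unrooted
bipartition multiset and the total branch length exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .align_edit import RenameMap
from .tree import Node, PhyloError, Tree

__all__ = [
    "TipSelection",
    "prune",
    "reroot_outgroup",
    "reroot_midpoint",
    "collapse",
    "rename_tips",
    "resolve",
    "random_tree",
]


@dataclass
class TipSelection:
    names: set
    mode: str = "remove"  # or "keep"

    def __post_init__(self) -> None:
        if self.mode not in ("remove", "keep"):
            raise PhyloError(f"unknown tip-selection mode: {self.mode!r}")
        if not self.names:
            raise PhyloError("empty tip selection")
        self.names = set(self.names)


# ---------------------------------------------------------------------------
# pruning


def prune(tree: Tree, sel: TipSelection, force: bool = False) -> Tree:
    """Remove the selected tips (or keep only them, mode ``keep``).

    Degree-2 nodes left behind are suppressed with branch lengths summed;
    when two edges merge, the support of the edge farther from the root is
    kept.  Patristic distances among surviving tips are unchanged.
    """
    present = set(tree.tip_names())
    unknown = sorted(sel.names - present)
    if unknown and not force:
        raise PhyloError(f"unknown tips: {', '.join(unknown)}")
    to_remove = (
        sel.names & present if sel.mode == "remove" else present - sel.names
    )
    if len(present) - len(to_remove) < 2:
        raise PhyloError("pruning would leave fewer than 2 tips")
    work = tree.copy()
    for tip in work.tips():
        if tip.label in to_remove:
            parent = tip.parent
            parent.remove_child(tip)
            # drop internal nodes emptied by tip removal
            while parent is not None and not parent.children:
                grand = parent.parent
                if grand is None:
                    raise PhyloError("cannot remove every tip")
                grand.remove_child(parent)
                parent = grand
    work.suppress_unifurcations()
    return work


# ---------------------------------------------------------------------------
# rerooting


def _reverse_path(node: Node) -> None:
    """Reverse every edge on the path from ``node`` up to the old root,
    making ``node`` a local root.  Edge lengths/supports travel with their
    edge."""
    parent = node.parent
    if parent is None:
        return
    old_len, old_sup = node.length, node.support
    parent.remove_child(node)
    _reverse_path(parent)
    node.add_child(parent)
    parent.length, parent.support = old_len, old_sup


def _reroot_at_edge(tree: Tree, child: Node, dist_from_child) -> Tree:
    """New root on the edge above ``child``, ``dist_from_child`` away from
    ``child``.  Call on a private copy: the tree is modified in place."""
    parent = child.parent
    if parent is None:
        raise PhyloError("cannot reroot at the root's own (absent) edge")
    edge_len, edge_sup = child.length, child.support
    parent.remove_child(child)
    new_root = Node()
    new_root.add_child(child)
    _reverse_path(parent)
    new_root.add_child(parent)
    if edge_len is not None:
        if not 0 <= dist_from_child <= edge_len + 1e-12:
            raise PhyloError("split point outside the target edge")
        child.length = float(dist_from_child)
        parent.length = max(edge_len - float(dist_from_child), 0.0)
    else:
        child.length = parent.length = None
    # both halves of the split edge carry the original edge's support
    child.support = parent.support = edge_sup
    tree.root = new_root
    tree.suppress_unifurcations()
    return tree


def reroot_outgroup(tree: Tree, outgroup) -> Tree:
    """Root on the edge above the minimal clade holding the outgroup.

    The attachment edge is split at its midpoint.  If the outgroup is not
    monophyletic in the result a warning is emitted and the root still
    separates the minimal clade found.
    """
    outgroup = set(outgroup)
    tips = set(tree.tip_names())
    if not outgroup:
        raise PhyloError("empty outgroup")
    missing = sorted(outgroup - tips)
    if missing:
        raise PhyloError(f"outgroup tips not in tree: {', '.join(missing)}")
    if outgroup == tips:
        raise PhyloError("outgroup cannot contain every tip")
    work = tree.copy()
    # provisional rooting at a non-outgroup tip so the outgroup MRCA is
    # a proper descendant
    anchor = next(t for t in work.tips() if t.label not in outgroup)
    work = _reroot_at_edge(
        work, anchor, anchor.length / 2 if anchor.length is not None else None
    )
    # minimal clade containing the whole outgroup: deepest node whose
    # subtree covers it
    cover: dict[int, set] = {}
    mrca = work.root
    for node in work.postorder():
        s = (
            {node.label}
            if node.is_tip
            else set().union(*(cover[id(c)] for c in node.children))
        )
        cover[id(node)] = s
        if outgroup <= s and node is not work.root:
            mrca = node
            break
    if mrca is work.root:
        raise PhyloError("outgroup has no attachment edge")
    result = _reroot_at_edge(
        work, mrca, mrca.length / 2 if mrca.length is not None else None
    )
    og_side = {t.label for t in _tips_below(result.root.children[0])}
    if og_side != outgroup and (set(result.tip_names()) - og_side) != outgroup:
        warnings.warn("outgroup is not monophyletic in the rerooted tree")
    return result


def _tips_below(node: Node):
    stack = [node]
    while stack:
        x = stack.pop()
        if x.is_tip:
            yield x
        stack.extend(x.children)


def reroot_midpoint(tree: Tree) -> Tree:
    """Root at the midpoint of the longest tip-to-tip path.

    Ties among equally longest paths are broken by the lexicographically
    smallest (sorted) pair of tip names.
    """
    if not tree.has_all_lengths():
        raise PhyloError("midpoint rooting requires all branch lengths")
    work = tree.copy()
    from .tree_metrics import patristic_matrix

    dm = patristic_matrix(work)
    best = None
    for i, a in enumerate(dm.names):
        for j in range(i + 1, len(dm.names)):
            pair = tuple(sorted((a, dm.names[j])))
            key = (-dm.matrix[i, j], pair)
            if best is None or key < best[0]:
                best = (key, a, dm.names[j], dm.matrix[i, j])
    _, name_a, name_b, diameter = best
    # walk the a->b path; the midpoint lies where the running distance
    # from a crosses diameter/2
    tip_a = work.find_tip(name_a)
    tip_b = work.find_tip(name_b)
    path_a = _path_to_root(tip_a)
    path_b = _path_to_root(tip_b)
    in_a = {id(n): i for i, n in enumerate(path_a)}
    k = next(i for i, n in enumerate(path_b) if id(n) in in_a)
    mrca = path_b[k]
    # edges on the path, ordered from a to b, as (child_node) entries
    edges = path_a[: in_a[id(mrca)]] + list(reversed(path_b[:k]))
    half = diameter / 2.0
    acc = 0.0
    from_a = True
    for idx, node in enumerate(edges):
        length = node.length or 0.0
        from_a = idx < in_a[id(mrca)]
        if acc + length >= half - 1e-12:
            offset = half - acc  # distance into this edge from its a-side end
            if from_a:
                dist_from_child = offset  # walking child -> parent
            else:
                dist_from_child = length - offset  # walking parent -> child
            dist_from_child = min(max(dist_from_child, 0.0), length)
            return _reroot_at_edge(work, node, dist_from_child)
        acc += length
    raise PhyloError("midpoint not found (inconsistent branch lengths)")


def _path_to_root(node: Node) -> list:
    path = []
    while node is not None:
        path.append(node)
        node = node.parent
    return path


# ---------------------------------------------------------------------------
# collapsing, renaming, resolving


def collapse(tree: Tree, criterion: str, cutoff: float) -> Tree:
    """Contract internal edges with length (or support) strictly below
    the cutoff, creating polytomies.  Tip edges are never collapsed and,
    for the support criterion, edges without a support value are kept.
    """
    if criterion not in ("length", "support"):
        raise PhyloError(f"unknown collapse criterion: {criterion!r}")
    if cutoff < 0:
        raise PhyloError("cutoff must be non-negative")
    work = tree.copy()
    for node in list(work.postorder()):
        if node.is_tip or node.parent is None:
            continue
        value = node.length if criterion == "length" else node.support
        if value is None or value >= cutoff:
            continue
        parent = node.parent
        idx = parent.children.index(node)
        for child in node.children:
            child.parent = parent
        parent.children[idx : idx + 1] = node.children
    return work


def rename_tips(tree: Tree, rename_map: RenameMap, allow_missing: bool = False) -> Tree:
    """Rename tip labels by map (see align_edit.rename_seqs for the contract)."""
    present = set(tree.tip_names())
    if not allow_missing:
        missing = [o for o in rename_map.mapping if o not in present]
        if missing:
            raise PhyloError(f"rename map entries match no tip: {', '.join(missing)}")
    work = tree.copy()
    for tip in work.tips():
        tip.label = rename_map.mapping.get(tip.label, tip.label)
    work.validate()
    return work


def resolve(tree: Tree, seed: int) -> Tree:
    """Randomly resolve polytomies with zero-length, support-free edges.

    Internal nodes are reduced to two children; an unrooted root (three or
    more children) is reduced to three so the tree stays unrooted.
    """
    rng = np.random.default_rng(seed)
    work = tree.copy()
    for node in list(work.postorder()):
        target = 3 if node is work.root and len(node.children) >= 3 else 2
        while len(node.children) > target:
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a, b = node.children[i], node.children[j]
            joint = Node(length=0.0)
            node.children[i] = joint
            del node.children[j]
            joint.parent = node
            joint.children = [a, b]
            a.parent = b.parent = joint
    return work


# ---------------------------------------------------------------------------
# random trees


def random_tree(n_tips: int, model: str = "yule", seed: int = 0) -> Tree:
    """Random or deterministic tree shapes with tips named T1..Tn.

    yule: iterative random tip splitting, exponential(1) branch lengths.
    uniform: topology uniform over rooted binary labeled topologies
    (sequential insertion on a uniformly chosen edge, the root edge
    included), exponential(1) lengths.  caterpillar/balanced: fixed shapes
    with unit branch lengths (balanced needs a power-of-two tip count).
    """
    if n_tips < 3:
        raise PhyloError("need at least 3 tips")
    if model == "caterpillar":
        node = Node("T1", 1.0)
        inner = Node(length=1.0)
        inner.add_child(node)
        inner.add_child(Node("T2", 1.0))
        for k in range(3, n_tips + 1):
            top = Node(length=1.0)
            top.add_child(inner)
            top.add_child(Node(f"T{k}", 1.0))
            inner = top
        inner.length = None
        return Tree(inner)
    if model == "balanced":
        if n_tips & (n_tips - 1):
            raise PhyloError("balanced trees need a power-of-two tip count")
        counter = [0]

        def build(size: int) -> Node:
            if size == 1:
                counter[0] += 1
                return Node(f"T{counter[0]}", 1.0)
            node = Node(length=1.0)
            node.add_child(build(size // 2))
            node.add_child(build(size // 2))
            return node

        root = build(n_tips)
        root.length = None
        return Tree(root)
    rng = np.random.default_rng(seed)
    if model == "yule":
        root = Node()
        tips = [root.add_child(Node("T1")), root.add_child(Node("T2"))]
        label = 3
        while len(tips) < n_tips:
            victim = tips.pop(rng.integers(len(tips)))
            tips.append(victim.add_child(Node(victim.label)))
            tips.append(victim.add_child(Node(f"T{label}")))
            victim.label = None
            label += 1
        tree = Tree(root)
        for node in tree.preorder():
            if node is not root:
                node.length = float(rng.exponential(1.0))
        return tree
    if model == "uniform":
        root = Node()
        root.add_child(Node("T1"))
        root.add_child(Node("T2"))
        for k in range(3, n_tips + 1):
            # candidate attachment points: every non-root node's edge,
            # plus the edge above the root
            nodes = [n for n in Tree(root).preorder() if n is not root]
            choice = int(rng.integers(len(nodes) + 1))
            tip = Node(f"T{k}")
            if choice == len(nodes):  # root edge: new root above everything
                new_root = Node()
                new_root.add_child(root)
                new_root.add_child(tip)
                root = new_root
            else:
                target = nodes[choice]
                parent = target.parent
                idx = parent.children.index(target)
                mid = Node()
                parent.children[idx] = mid
                mid.parent = parent
                mid.add_child(target)
                mid.add_child(tip)
        tree = Tree(root)
        for node in tree.preorder():
            if node is not root:
                node.length = float(rng.exponential(1.0))
        return tree
    raise PhyloError(f"unknown tree model: {model!r}")
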