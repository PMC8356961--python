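"""Bootstrap branch supports on a reference tree.

Two supports are implemented.  The Felsenstein bootstrap proportion (FBP)
of a reference branch is the fraction of bootstrap trees containing its
exact bipartition.  The transfer bootstrap expectation (TBE) of a branch b
with light-side size p is the mean over bootstrap trees T of

    1 - delta(b, T) / (p - 1),

where delta is the transfer distance: the minimum Hamming distance between
the indicator vector of b and that of any branch of T (tip branches
included), minimized over the two orientations.  delta is at most p-1, so
the support lies in [0, 1]; it equals the FBP contribution (0 or 1) for
cherries (p = 2) and never falls below it.

Splits are held as integer bitmasks, so transfer distances reduce to XOR
plus popcount over all bootstrap edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tree import PhyloError, Tree, TreeList

__all__ = ["SupportResult", "EdgeDiagnostic", "fbp", "tbe", "transfer_distance"]


@dataclass
class EdgeDiagnostic:
    edge_id: int
    side: frozenset  # light side tip names
    p: int
    support: float
    mean_transfer: float | None = None  # TBE only


@dataclass
class SupportResult:
    tree: Tree
    method: str
    n_boots: int
    diagnostics: list = field(default_factory=list)


def _tip_index(tree: Tree) -> dict:
    return {name: i for i, name in enumerate(sorted(tree.tip_names()))}


def _edge_masks(tree: Tree, index: dict, include_tips: bool):
    """Bitmask of the tip set below each non-root node (postorder)."""
    masks = []
    clades: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_tip:
            m = 1 << index[node.label]
        else:
            m = 0
            for c in node.children:
                m |= clades[id(c)]
        clades[id(node)] = m
        if node.parent is not None and (include_tips or not node.is_tip):
            masks.append(m)
    return masks


def _canonical(mask: int, full: int) -> int:
    # orient away from bit 0 (the lexicographically smallest tip)
    return mask ^ full if mask & 1 else mask


def _check_boots(ref: Tree, boots: TreeList) -> None:
    if not boots:
        raise PhyloError("no bootstrap trees given")
    ref_tips = set(ref.tip_names())
    for i, boot in enumerate(boots, 1):
        if set(boot.tip_names()) != ref_tips:
            raise PhyloError(
                f"bootstrap tree {i} has a different tip set than the reference"
            )


def _ref_edges(ref: Tree, index: dict):
    """(nodes, mask, p) per non-trivial split of the reference.

    The two edges flanking a bifurcating root induce the same split: both
    nodes are annotated but the split is reported once.
    """
    n = len(index)
    full = (1 << n) - 1
    groups: dict[int, list] = {}
    order: list[int] = []
    clades: dict[int, int] = {}
    masks: dict[int, int] = {}
    for node in ref.postorder():
        if node.is_tip:
            clades[id(node)] = 1 << index[node.label]
            continue
        m = 0
        for c in node.children:
            m |= clades[id(c)]
        clades[id(node)] = m
        size = m.bit_count()
        if node.parent is None or size < 2 or size > n - 2:
            continue
        canon = _canonical(m, full)
        if canon not in groups:
            groups[canon] = []
            order.append(canon)
            masks[canon] = m
        groups[canon].append(node)
    return [
        (groups[c], masks[c],
         min(masks[c].bit_count(), n - masks[c].bit_count()))
        for c in order
    ]


def _light_side(mask: int, full: int, names) -> frozenset:
    """Tip names of the smaller side; exact halves break the tie toward
    the side not containing the lexicographically smallest tip."""
    n = len(names)
    size = mask.bit_count()
    if size * 2 == n:
        light = _canonical(mask, full)
    elif size * 2 < n:
        light = mask
    else:
        light = mask ^ full
    return frozenset(names[i] for i in range(n) if light >> i & 1)


def fbp(ref: Tree, boots: TreeList) -> SupportResult:
    """Felsenstein bootstrap proportions, annotated on a copy of ``ref``."""
    _check_boots(ref, boots)
    work = ref.copy()
    index = _tip_index(work)
    full = (1 << len(index)) - 1
    boot_sets = []
    for boot in boots:
        masks = _edge_masks(boot, index, include_tips=False)
        boot_sets.append(
            {
                _canonical(m, full)
                for m in masks
                if 2 <= m.bit_count() <= len(index) - 2
            }
        )
    result = SupportResult(work, "fbp", len(boots))
    names = sorted(index, key=index.get)
    for eid, (nodes, mask, p) in enumerate(_ref_edges(work, index)):
        canon = _canonical(mask, full)
        count = sum(canon in s for s in boot_sets)
        support = count / len(boots)
        for node in nodes:
            node.support = support
        side = _light_side(mask, full, names)
        result.diagnostics.append(EdgeDiagnostic(eid, side, p, support))
    return result


def transfer_distance(side, tree: Tree) -> int:
    """Minimum tip moves turning the split ``side | rest`` into a split of
    ``tree``; tip edges count as candidate splits."""
    side = set(side)
    tips = set(tree.tip_names())
    if not side <= tips:
        raise PhyloError("bipartition names not in the tree's tip set")
    index = {name: i for i, name in enumerate(sorted(tips))}
    full = (1 << len(index)) - 1
    b = 0
    for name in side:
        b |= 1 << index[name]
    return _transfer_distance_mask(b, _edge_masks(tree, index, True), full)


def _transfer_distance_mask(b: int, masks, full: int) -> int:
    best = full.bit_count()
    for m in masks:
        x = b ^ m
        d = x.bit_count()
        d2 = (x ^ full).bit_count()
        if d2 < d:
            d = d2
        if d < best:
            best = d
            if best == 0:
                return 0
    return best


def tbe(ref: Tree, boots: TreeList) -> SupportResult:
    """Transfer bootstrap expectation, annotated on a copy of ``ref``."""
    _check_boots(ref, boots)
    work = ref.copy()
    index = _tip_index(work)
    full = (1 << len(index)) - 1
    boot_masks = [_edge_masks(b, index, include_tips=True) for b in boots]
    result = SupportResult(work, "tbe", len(boots))
    names = sorted(index, key=index.get)
    for eid, (nodes, mask, p) in enumerate(_ref_edges(work, index)):
        total = 0
        for masks in boot_masks:
            total += _transfer_distance_mask(mask, masks, full)
        mean_delta = total / len(boots)
        support = min(max(1.0 - mean_delta / (p - 1), 0.0), 1.0)
        for node in nodes:
            node.support = support
        side = _light_side(mask, full, names)
        result.diagnostics.append(
            EdgeDiagnostic(eid, side, p, support, mean_delta)
        )
    return result
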