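"""Independent test oracles: brute-force implementations kept deliberately
separate from the package's own code paths."""

from __future__ import annotations

import itertools
import math

import numpy as np

from phylokit.tree import Tree
from phylokit.treeio import parse_newick


# ---------------------------------------------------------------------------
# bipartitions / RF by plain enumeration


def tips_below(node):
    out = []
    stack = [node]
    while stack:
        x = stack.pop()
        if not x.children:
            out.append(x.label)
        stack.extend(x.children)
    return out


def naive_splits(tree: Tree) -> set:
    """Non-trivial splits as frozensets-of-both-sides (orientation-free)."""
    universe = frozenset(tree.tip_names())
    n = len(universe)
    out = set()
    for node in tree.preorder():
        if node is tree.root or node.is_tip:
            continue
        below = frozenset(tips_below(node))
        if 2 <= len(below) <= n - 2:
            out.add(frozenset((below, universe - below)))
    return out


def naive_rf(t1: Tree, t2: Tree) -> int:
    s1, s2 = naive_splits(t1), naive_splits(t2)
    return len(s1 ^ s2)


# ---------------------------------------------------------------------------
# transfer distance / TBE by brute force


def naive_all_splits_with_tips(tree: Tree) -> list:
    """Tip set below every non-root node, tip edges included."""
    out = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        out.append(frozenset(tips_below(node)))
    return out


def naive_transfer_distance(side, tree: Tree) -> int:
    side = frozenset(side)
    universe = frozenset(tree.tip_names())
    best = len(universe)
    for below in naive_all_splits_with_tips(tree):
        d = min(len(side ^ below), len(side ^ (universe - below)))
        best = min(best, d)
    return best


def naive_transfer_distance_np(side, tree: Tree) -> int:
    """Same oracle, vectorized with boolean indicator matrices."""
    names = sorted(tree.tip_names())
    idx = {nm: i for i, nm in enumerate(names)}
    b = np.zeros(len(names), dtype=bool)
    for nm in side:
        b[idx[nm]] = True
    rows = []
    for below in naive_all_splits_with_tips(tree):
        row = np.zeros(len(names), dtype=bool)
        for nm in below:
            row[idx[nm]] = True
        rows.append(row)
    mat = np.array(rows)
    ham = np.sum(mat ^ b, axis=1)
    return int(np.minimum(ham, len(names) - ham).min())


def _light(below, universe):
    other = universe - below
    if len(below) < len(other):
        return below
    if len(other) < len(below):
        return other
    return below if min(universe) not in below else other


def naive_tbe_supports(ref: Tree, boots) -> list:
    """(light-side set, support) per non-trivial internal edge of ref."""
    universe = frozenset(ref.tip_names())
    n = len(universe)
    out = []
    for node in ref.preorder():
        if node is ref.root or node.is_tip:
            continue
        below = frozenset(tips_below(node))
        if not 2 <= len(below) <= n - 2:
            continue
        light = _light(below, universe)
        p = len(light)
        deltas = [naive_transfer_distance(below, b) for b in boots]
        support = sum(1.0 - d / (p - 1) for d in deltas) / len(boots)
        out.append((light, min(max(support, 0.0), 1.0)))
    return out


def naive_fbp_supports(ref: Tree, boots) -> list:
    universe = frozenset(ref.tip_names())
    n = len(universe)
    boot_splits = [naive_splits(b) for b in boots]
    out = []
    for node in ref.preorder():
        if node is ref.root or node.is_tip:
            continue
        below = frozenset(tips_below(node))
        if not 2 <= len(below) <= n - 2:
            continue
        split = frozenset((below, universe - below))
        light = _light(below, universe)
        out.append((light, sum(split in s for s in boot_splits) / len(boots)))
    return out


# ---------------------------------------------------------------------------
# tree enumeration and depth oracles


def all_unrooted_5tip_trees() -> list:
    """The 15 distinct unrooted binary topologies on tips A..E."""
    shapes = []
    # quartet on 4 of the tips, 5th inserted on each of the 5 edges --
    # generate instead by sequential insertion, which enumerates exactly
    # the (2n-5)!! unrooted topologies
    def insert(newick_edges, tips):
        # represent a tree as nested tuples with an (a,b,c) unrooted core
        pass

    # simpler: enumerate quartet topologies x insertion edges via newick text
    out = set()
    tips = list("ABCDE")
    for quartet_split in [("A", "B"), ("A", "C"), ("A", "D"), ("A", "E"),
                          ("B", "C"), ("B", "D"), ("B", "E"),
                          ("C", "D"), ("C", "E"), ("D", "E")]:
        rest = [t for t in tips if t not in quartet_split]
        a, b = quartet_split
        c, d, e = rest
        # unrooted 5-tip trees have two cherries; enumerate all cherry pairs
        for other in itertools.combinations(rest, 2):
            x, y = other
            mid = next(t for t in rest if t not in other)
            nwk = f"(({a},{b}),{mid},({x},{y}));"
            tree = parse_newick(nwk)
            key = frozenset(naive_splits(tree))
            if key not in out:
                out.add(key)
                shapes.append(tree)
    assert len(shapes) == 15
    return shapes


def tip_depths(tree: Tree) -> dict:
    """Root-to-tip edge counts by following parent pointers."""
    depths = {}
    for tip in tree.tips():
        d = 0
        node = tip
        while node.parent is not None:
            d += 1
            node = node.parent
        depths[tip.label] = d
    return depths


# ---------------------------------------------------------------------------
# independently coded closed forms (different algebraic arrangement)


def jc_oracle(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k2p_oracle(P: float, Q: float) -> float:
    w1 = 1.0 / (1.0 - 2.0 * P - Q)
    w2 = 1.0 / (1.0 - 2.0 * Q)
    return 0.5 * math.log(w1) + 0.25 * math.log(w2)


def f81_oracle(p: float, pi) -> float:
    e = 1.0 - sum(x * x for x in pi)
    return -e * math.log1p(-p / e)


def f84_oracle(P: float, Q: float, pi) -> float:
    pa, pc, pg, pt = pi
    r, y = pa + pg, pc + pt
    a = pa * pg / r + pc * pt / y
    b = pa * pg + pc * pt
    c = r * y
    t1 = math.log1p(-(P / (2 * a) + (a - b) * Q / (2 * a * c)))
    t2 = math.log1p(-Q / (2 * c))
    return -2 * a * t1 + 2 * (a - b - c) * t2


def tn93_oracle(P1: float, P2: float, Q: float, pi) -> float:
    pa, pc, pg, pt = pi
    r, y = pa + pg, pc + pt
    a1 = 2 * pa * pg / r
    a2 = 2 * pc * pt / y
    b = 2 * r * y - a1 * y - a2 * r
    t1 = math.log1p(-(P1 / a1 + Q / (2 * r)))
    t2 = math.log1p(-(P2 / a2 + Q / (2 * y)))
    t3 = math.log1p(-Q / (2 * r * y))
    return -a1 * t1 - a2 * t2 - b * t3


def poisson20_oracle(p: float) -> float:
    return -(19.0 / 20.0) * math.log1p(-20.0 * p / 19.0)


def tn93_expected_proportions(d: float, pi, kappa1: float, kappa2: float):
    """Forward model: expected (P1, P2, Q) at distance d under TN93,
    computed by numerical matrix exponentiation of the rate matrix."""
    from scipy.linalg import expm

    pi = np.asarray(pi, dtype=float)
    # order ACGT; transitions A<->G rate kappa1, C<->T rate kappa2
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = 1.0
            if {i, j} == {0, 2}:
                rate = kappa1
            elif {i, j} == {1, 3}:
                rate = kappa2
            q[i, j] = rate * pi[j]
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    q /= scale
    p = expm(q * d)
    joint = pi[:, None] * p
    P1 = joint[0, 2] + joint[2, 0]
    P2 = joint[1, 3] + joint[3, 1]
    Q = 1.0 - np.trace(joint) - P1 - P2
    return float(P1), float(P2), float(Q)
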