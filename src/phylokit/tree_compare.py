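"""Bipartition extraction and topology comparison.

A bipartition (split) is the two-way partition of the tip set induced by
an internal edge of the unrooted tree.  Splits are canonicalized as the
side NOT containing the lexicographically smallest tip name, which makes
equality deterministic and orientation-free.  The bipartition (Robinson-
Foulds) distance is the number of non-trivial splits present in exactly
one of the two trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .tree import PhyloError, Tree

__all__ = [
    "Bipartition",
    "ComparisonResult",
    "bipartitions",
    "compare_trees",
    "compare_tips",
]


@dataclass(frozen=True)
class Bipartition:
    """Canonical side of a split plus the full tip universe size."""

    side: frozenset
    n_taxa: int

    @property
    def p(self) -> int:
        """Size of the light (smaller) side."""
        return min(len(self.side), self.n_taxa - len(self.side))

    @property
    def is_trivial(self) -> bool:
        return len(self.side) < 2 or len(self.side) > self.n_taxa - 2


def bipartitions(tree: Tree) -> set:
    """Non-trivial canonical bipartitions, one per internal edge.

    The two edges flanking a bifurcating root induce the same split and
    contribute a single bipartition.
    """
    names = tree.tip_names()
    n = len(names)
    universe = set(names)
    smallest = min(universe)
    out = set()
    clades: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip:
            clades[id(node)] = frozenset((node.label,))
            continue
        clade = frozenset().union(*(clades[id(c)] for c in node.children))
        clades[id(node)] = clade
        if node.parent is None:
            continue
        if len(clade) < 2 or len(clade) > n - 2:
            continue
        side = clade if smallest not in clade else frozenset(universe - clade)
        out.add(Bipartition(side, n))
    return out


@dataclass
class ComparisonResult:
    n_common: int
    n_ref_only: int
    n_comp_only: int

    @property
    def rf_distance(self) -> int:
        return self.n_ref_only + self.n_comp_only


def compare_trees(ref: Tree, comp: Tree) -> ComparisonResult:
    """Bipartition-set comparison; trees are compared as unrooted."""
    ref_tips = set(ref.tip_names())
    comp_tips = set(comp.tip_names())
    if ref_tips != comp_tips:
        only_r = sorted(ref_tips - comp_tips)
        only_c = sorted(comp_tips - ref_tips)
        raise PhyloError(
            f"tip sets differ: only in reference {only_r}, only in comparison {only_c}"
        )
    ref_bp = bipartitions(ref)
    comp_bp = bipartitions(comp)
    common = ref_bp & comp_bp
    return ComparisonResult(
        n_common=len(common),
        n_ref_only=len(ref_bp) - len(common),
        n_comp_only=len(comp_bp) - len(common),
    )


def compare_tips(t1: Tree, t2: Tree):
    """Tip-name set differences: (only_in_1, only_in_2, common)."""
    s1, s2 = set(t1.tip_names()), set(t2.tip_names())
    common = s1 & s2
    if not common:
        warnings.warn("the two trees share no tip names")
    return s1 - s2, s2 - s1, common
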