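"""Tree editing: pruning, rerooting, collapsing, renaming, resolving,
random generation."""

import math

import numpy as np
import pytest

from conftest import random_trees
from helpers import naive_splits
from phylokit.align_edit import RenameMap
from phylokit.tree import PhyloError
from phylokit.tree_edit import (
    TipSelection,
    collapse,
    prune,
    random_tree,
    rename_tips,
    reroot_midpoint,
    reroot_outgroup,
    resolve,
)
from phylokit.tree_metrics import colless, patristic_matrix
from phylokit.treeio import parse_newick, write_newick


class TestPrune:
    def test_path_merge(self):
        t = parse_newick("((A:1,B:2):3,C:4);")
        assert write_newick(prune(t, TipSelection({"B"}))) == "(A:4,C:4);"

    def test_patristic_conservation_small(self):
        t = parse_newick("((A:1,B:2):3,C:4);")
        before = patristic_matrix(t)[("A", "C")]
        after = patristic_matrix(prune(t, TipSelection({"B"})))[("A", "C")]
        assert before == after == 8

    def test_unknown_tip_needs_force(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(PhyloError):
            prune(t, TipSelection({"Z"}))
        pruned = prune(t, TipSelection({"Z", "A"}), force=True)
        assert sorted(pruned.tip_names()) == ["B", "C"]

    def test_keep_mode(self):
        t = parse_newick("((A:1,B:2):3,(C:4,D:5):6);")
        kept = prune(t, TipSelection({"A", "C"}, "keep"))
        assert sorted(kept.tip_names()) == ["A", "C"]

    def test_too_few_survivors(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(PhyloError):
            prune(t, TipSelection({"A", "B"}))

    def test_patristic_conservation_random(self):
        rng = np.random.default_rng(5150)
        for k in range(100):
            tree = random_trees(1, 12, 9000 + k)[0]
            names = tree.tip_names()
            drop = set(rng.choice(names, size=4, replace=False))
            keep = [n for n in names if n not in drop]
            before = patristic_matrix(tree)
            after = patristic_matrix(prune(tree, TipSelection(drop)))
            for i, a in enumerate(keep):
                for b in keep[i + 1:]:
                    assert after[(a, b)] == pytest.approx(before[(a, b)], abs=1e-9)

    def test_support_of_farther_edge_kept(self):
        t = parse_newick("(((A:1,B:1)0.8:1,C:1)0.3:1,(D:1,E:1):1);")
        pruned = prune(t, TipSelection({"C"}))
        # (A,B) node's parent edge merged with its own: keeps 0.8 (farther)
        node = next(
            n for n in pruned.preorder()
            if sorted(t2.label for t2 in n.children if t2.is_tip) == ["A", "B"]
        )
        assert node.support == 0.8


class TestRerootOutgroup:
    def test_compatible_split(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        r = reroot_outgroup(t, {"C", "D"})
        sides = [sorted(tip.label for tip in _tips(c)) for c in r.root.children]
        assert ["C", "D"] in sides

    def test_single_tip_outgroup_on_unrooted(self):
        t = parse_newick("(A:1,B:2,(C:1,D:1):1);")
        r = reroot_outgroup(t, {"A"})
        assert r.is_rooted
        assert naive_splits(r) == naive_splits(t)
        assert r.total_length() == pytest.approx(t.total_length())

    def test_all_tips_outgroup_rejected(self):
        with pytest.raises(PhyloError):
            reroot_outgroup(parse_newick("((A,B),(C,D));"), {"A", "B", "C", "D"})

    def test_non_monophyletic_outgroup_warns(self):
        t = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        with pytest.warns(UserWarning):
            reroot_outgroup(t, {"A", "B"})

    def test_invariants_random(self):
        rng = np.random.default_rng(31)
        for k in range(50):
            tree = random_trees(1, 10, 4000 + k)[0]
            names = tree.tip_names()
            og = set(rng.choice(names, size=int(rng.integers(1, 5)), replace=False))
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                r = reroot_outgroup(tree, og)
            assert naive_splits(r) == naive_splits(tree)
            assert r.total_length() == pytest.approx(tree.total_length(), abs=1e-9)


class TestRerootMidpoint:
    def test_symmetric_tree(self):
        r = reroot_midpoint(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        d = patristic_matrix(r)
        # root equidistant from the two farthest tips
        assert _max_root_depth_gap(r) <= 1e-9
        assert d[("A", "C")] == 4

    def test_two_tip_midpoint(self):
        r = reroot_midpoint(parse_newick("(A:1,B:5);"))
        depths = _root_depths(r)
        assert depths["A"] == pytest.approx(3) and depths["B"] == pytest.approx(3)

    def test_missing_length_rejected(self):
        with pytest.raises(PhyloError):
            reroot_midpoint(parse_newick("((A:1,B),C:2);"))

    def test_balanced_depths_random(self):
        for k in range(40):
            tree = random_trees(1, 12, 600 + k)[0]
            r = reroot_midpoint(tree)
            assert _max_root_depth_gap(r) <= 1e-9
            assert naive_splits(r) == naive_splits(tree)
            assert r.total_length() == pytest.approx(tree.total_length(), abs=1e-9)


class TestCollapse:
    def test_support_cutoff(self):
        t = parse_newick("((A,B)0.3:1,(C,D)0.9:1,E);")
        assert write_newick(collapse(t, "support", 0.7)) == "(A,B,(C,D)0.9:1,E);"

    def test_strict_boundary(self):
        t = parse_newick("((A,B):0,(C,D):1,E);")
        assert write_newick(collapse(t, "length", 0.0)) == write_newick(t)

    def test_unsupported_edges_never_collapsed(self):
        t = parse_newick("((A,B):1,(C,D)0.9:1,E);")
        out = collapse(t, "support", 0.95)
        # (A,B) kept (no support), (C,D) collapsed (0.9 < 0.95)
        assert write_newick(out) == "((A,B):1,C,D,E);"

    def test_tip_set_and_length_sum_preserved(self):
        for k in range(30):
            tree = random_trees(1, 15, 80 + k)[0]
            cut = 0.5
            out = collapse(tree, "length", cut)
            assert sorted(out.tip_names()) == sorted(tree.tip_names())
            kept = sum(
                n.length for n in out.preorder()
                if n.length is not None
            )
            expect = sum(
                n.length for n in tree.preorder()
                if n.length is not None and not (
                    not n.is_tip and n.parent is not None and n.length < cut
                )
            )
            assert kept == pytest.approx(expect, abs=1e-9)

    def test_negative_cutoff(self):
        with pytest.raises(PhyloError):
            collapse(parse_newick("((A,B),C);"), "length", -1)


class TestRenameResolve:
    def test_rename_tips(self):
        t = parse_newick("((A,B),C);")
        out = rename_tips(t, RenameMap([("A", "X")]))
        assert sorted(out.tip_names()) == ["B", "C", "X"]
        assert naive_splits(out) == set()  # topology structure untouched

    def test_rename_collision(self):
        with pytest.raises(PhyloError):
            rename_tips(parse_newick("((A,B),C);"), RenameMap([("A", "B")]))

    def test_rename_missing_flag(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(PhyloError):
            rename_tips(t, RenameMap([("Z", "Y")]))
        out = rename_tips(t, RenameMap([("Z", "Y")]), allow_missing=True)
        assert sorted(out.tip_names()) == ["A", "B", "C"]

    def test_resolve_star(self):
        t = resolve(parse_newick("(A,B,C,D);"), seed=3)
        degrees = [len(n.children) for n in t.preorder() if n.children]
        assert max(degrees) <= 3 and degrees[0] == 3
        new_edges = [n for n in t.preorder() if n.length == 0.0]
        assert 1 <= len(new_edges) <= 2

    def test_resolve_binary_identity(self):
        t = parse_newick("((A:1,B:2):3,C:4);")
        assert write_newick(resolve(t, seed=1)) == write_newick(t)

    def test_resolve_deterministic(self):
        t = parse_newick("(A,B,C,D,E,F,G);")
        assert write_newick(resolve(t, 11)) == write_newick(resolve(t, 11))


class TestRandomTree:
    @pytest.mark.parametrize("model", ["yule", "uniform", "caterpillar", "balanced"])
    def test_rooted_binary_counts(self, model):
        t = random_tree(8, model, seed=4)
        assert t.n_tips == 8
        assert sum(1 for n in t.preorder() if n.children) == 7
        assert sorted(t.tip_names()) == [f"T{i}" for i in range(1, 9)]
        assert t.is_rooted

    def test_caterpillar_colless(self):
        assert colless(random_tree(5, "caterpillar")) == 6

    def test_balanced_colless_zero(self):
        assert colless(random_tree(4, "balanced")) == 0

    def test_balanced_needs_power_of_two(self):
        with pytest.raises(PhyloError):
            random_tree(6, "balanced")

    def test_too_few_tips(self):
        with pytest.raises(PhyloError):
            random_tree(2, "yule")

    def test_seeded_determinism(self):
        a = write_newick(random_tree(20, "yule", seed=5))
        assert a == write_newick(random_tree(20, "yule", seed=5))
        assert a != write_newick(random_tree(20, "yule", seed=6))

    def test_uniform_topology_frequencies(self):
        """On 5 tips each of the 105 rooted labeled topologies appears with
        frequency 1/105 (within 0.01) over 10,000 draws."""
        from collections import Counter

        def topo_key(tree):
            def canon(node):
                if node.is_tip:
                    return node.label
                return "(" + ",".join(sorted(canon(c) for c in node.children)) + ")"

            return canon(tree.root)

        counts = Counter(
            topo_key(random_tree(5, "uniform", seed=k)) for k in range(10000)
        )
        assert len(counts) == 105
        for freq in counts.values():
            assert abs(freq / 10000 - 1 / 105) <= 0.01


def _tips(node):
    stack = [node]
    while stack:
        x = stack.pop()
        if not x.children:
            yield x
        stack.extend(x.children)


def _root_depths(tree):
    depths = {}
    stack = [(tree.root, 0.0)]
    while stack:
        node, d = stack.pop()
        if node.is_tip:
            depths[node.label] = d
        for c in node.children:
            stack.append((c, d + (c.length or 0.0)))
    return depths


def _max_root_depth_gap(tree):
    """Difference between the deepest tips on each side of the root."""
    sides = []
    for child in tree.root.children:
        depths = []
        stack = [(child, child.length or 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_tip:
                depths.append(d)
            for c in node.children:
                stack.append((c, d + (c.length or 0.0)))
        sides.append(max(depths))
    return abs(sides[0] - sides[1]) if len(sides) == 2 else math.inf
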