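"""Phylogenetic tree data model.

A :class:`Tree` is a rooted edge-weighted tree of :class:`Node` objects.  A
tree whose root has exactly two children is considered *rooted* in the
biological sense; a root of degree three or more marks an unrooted tree
(the standard Newick convention).  Branch lengths and branch supports live
on the edge between a node and its parent and are stored on the child node.
"""

from __future__ import annotations

from typing import Iterator, Optional


class PhyloError(ValueError):
    """Base error for invalid phylogenetic data or operations."""


class Node:
    """Single tree node: a tip (no children) or an internal node."""

    __slots__ = ("label", "children", "parent", "length", "support")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind}>"


class Tree:
    """Rooted or unrooted phylogenetic tree with unique tip labels."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.label for n in self.tips()]  # type: ignore[misc]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    # -- properties --------------------------------------------------------

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.preorder() if n.is_tip)

    def total_length(self) -> float:
        """Sum of all defined branch lengths."""
        return sum(n.length for n in self.preorder() if n.length is not None)

    def has_all_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.preorder() if n is not self.root
        )

    # -- editing helpers ---------------------------------------------------

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return Tree(_copy(self.root))

    def find_tip(self, name: str) -> Node:
        for tip in self.tips():
            if tip.label == name:
                return tip
        raise PhyloError(f"tip {name!r} not found in tree")

    def suppress_unifurcations(self) -> None:
        """Remove degree-2 non-root internal nodes, summing branch lengths.

        When an edge above and below a suppressed node merge, the support of
        the lower edge (farther from the root) is kept.
        """
        for node in list(self.postorder()):
            if node is self.root or node.is_tip:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                parent = node.parent
                assert parent is not None
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
        # root with a single child: lift the child up to be the new root
        while len(self.root.children) == 1 and not self.root.children[0].is_tip:
            child = self.root.children[0]
            child.parent = None
            child.length = None
            child.support = None
            self.root = child

    def validate(self) -> None:
        names = self.tip_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PhyloError(f"duplicate tip labels: {', '.join(dupes)}")
        if any(not n for n in names):
            raise PhyloError("empty tip label")
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise PhyloError(f"negative branch length on {node.label!r}")


class TreeList(list):
    """Ordered collection of trees, e.g. bootstrap replicates."""

    def __init__(self, trees=()):
        super().__init__(trees)
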