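"""Newick and Nexus tree reading and writing.

Conventions follow the dominant bootstrap-pipeline Newick dialect:

* an internal-node label that parses as a finite number is interpreted as
  the branch support of the edge above that node, otherwise it is kept as
  an internal node name;
* square-bracket comments are skipped, not preserved;
* labels containing whitespace or Newick metacharacters are single-quoted
  on output; underscores are never translated to spaces;
* gzip input is detected by magic bytes, never by file extension.
"""

from __future__ import annotations

import gzip
import io
import math
import re
from typing import IO, Iterable, Union

from .tree import Node, PhyloError, Tree, TreeList

__all__ = [
    "parse_newick",
    "write_newick",
    "read_trees",
    "write_trees",
    "NewickParseError",
]

_METACHARS = set("()[]{}:;,='\t\n ")


class NewickParseError(PhyloError):
    """Malformed Newick input; carries the offending position."""

    def __init__(self, message: str, pos: int) -> None:
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


# ---------------------------------------------------------------------------
# number formatting: shortest round-trippable decimal, positional notation
# for magnitudes >= 1e-4


def format_number(x: float) -> str:
    if x == math.inf:
        return "Inf"
    s = repr(float(x))
    if s.endswith(".0"):
        s = s[:-2]
    if "e" in s or "E" in s:
        if x != 0 and abs(x) >= 1e-4:
            for prec in range(1, 18):
                cand = f"{x:.{prec}f}"
                if float(cand) == x:
                    return cand.rstrip("0").rstrip(".")
            return f"{x:.17f}"
    return s


def _quote_label(label: str) -> str:
    if label and not (_METACHARS & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


# ---------------------------------------------------------------------------
# parsing


def _strip_comments(text: str) -> str:
    out = []
    depth = 0
    in_quote = False
    for i, ch in enumerate(text):
        if in_quote:
            out.append(ch)
            if ch == "'":
                in_quote = False  # '' escapes resume quoting on next char
            continue
        if ch == "'" and depth == 0:
            in_quote = True
            out.append(ch)
        elif ch == "[":
            depth += 1
        elif ch == "]":
            if depth == 0:
                raise NewickParseError("unbalanced ']' comment delimiter", i)
            depth -= 1
        elif depth == 0:
            out.append(ch)
    if depth:
        raise NewickParseError("unterminated '[' comment", len(text))
    return "".join(out)


_UNQUOTED_LABEL = re.compile(r"[^()\[\]:;,\s]+")
_NUMBER = re.compile(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?")


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickParseError:
        return NewickParseError(msg, self.pos)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def read_label(self) -> str:
        self.skip_ws()
        if self.peek() == "'":
            self.pos += 1
            chars = []
            while True:
                if self.pos >= len(self.text):
                    raise self.error("unterminated quoted label")
                ch = self.text[self.pos]
                if ch == "'":
                    if self.text[self.pos + 1 : self.pos + 2] == "'":
                        chars.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    return "".join(chars)
                chars.append(ch)
                self.pos += 1
        m = _UNQUOTED_LABEL.match(self.text, self.pos)
        if not m:
            return ""
        self.pos = m.end()
        return m.group()

    def read_number(self, what: str) -> float:
        self.skip_ws()
        m = _NUMBER.match(self.text, self.pos)
        if not m:
            raise self.error(f"expected {what}")
        self.pos = m.end()
        return float(m.group())

    def parse_clade(self) -> Node:
        node = Node()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.add_child(self.parse_clade())
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                raise self.error("expected ',' or ')' (unbalanced parentheses?)")
            label = self.read_label()
            if label:
                try:
                    support = float(label)
                except ValueError:
                    node.label = label
                else:
                    if math.isfinite(support):
                        node.support = support
                    else:
                        node.label = label
        else:
            label = self.read_label()
            if not label:
                raise self.error("expected a tip label")
            node.label = label
        if self.peek() == ":":
            self.pos += 1
            node.length = self.read_number("branch length after ':'")
        return node

    def parse_tree(self) -> Tree:
        self.skip_ws()
        if self.pos >= len(self.text):
            raise self.error("empty Newick input")
        root = self.parse_clade()
        if self.peek() != ";":
            raise self.error("expected ';' terminating the tree")
        self.pos += 1
        if root.is_tip and root.label is None:
            raise self.error("empty Newick statement")
        tree = Tree(root)
        tree.validate()
        return tree


def parse_newick(text: str) -> Tree:
    """Parse one complete Newick statement (must end in ``;``)."""
    parser = _Parser(_strip_comments(text))
    tree = parser.parse_tree()
    parser.skip_ws()
    if parser.pos < len(parser.text):
        raise parser.error("trailing characters after ';'")
    return tree


# ---------------------------------------------------------------------------
# writing


def _write_clade(node: Node, out: list) -> None:
    if node.children:
        out.append("(")
        for i, child in enumerate(node.children):
            if i:
                out.append(",")
            _write_clade(child, out)
        out.append(")")
        if node.support is not None:
            out.append(format_number(node.support))
        elif node.label is not None:
            out.append(_quote_label(node.label))
    else:
        out.append(_quote_label(node.label or ""))
    if node.length is not None:
        out.append(":" + format_number(node.length))


def write_newick(tree: Tree) -> str:
    """Serialize a tree as one Newick statement (no trailing newline)."""
    out: list = []
    _write_clade(tree.root, out)
    out.append(";")
    return "".join(out)


# ---------------------------------------------------------------------------
# multi-tree files: Newick (one statement per ';') and Nexus TREES block


def _decode_stream(stream: Union[str, bytes, IO]) -> str:
    """Return text content; transparently gunzip when magic bytes found."""
    if isinstance(stream, str):
        return stream
    if isinstance(stream, bytes):
        data = stream
    else:
        data = stream.read()
        if isinstance(data, str):
            return data
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data.decode("utf-8")


def _iter_newick_statements(text: str) -> Iterable[str]:
    depth = 0
    in_quote = False
    start = 0
    for i, ch in enumerate(text):
        if in_quote:
            if ch == "'":
                in_quote = False
            continue
        if ch == "'":
            in_quote = True
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == ";" and depth == 0:
            yield text[start : i + 1]
            start = i + 1
    tail = text[start:].strip()
    if tail:
        raise NewickParseError("garbage after last tree statement", start)


def _parse_nexus_trees(text: str) -> TreeList:
    m = re.search(r"begin\s+trees\s*;(.*?)\bend\s*;", text, re.IGNORECASE | re.DOTALL)
    if not m:
        raise PhyloError("no TREES block found in Nexus input")
    block = m.group(1)
    translate: dict[str, str] = {}
    tm = re.search(r"\btranslate\b(.*?);", block, re.IGNORECASE | re.DOTALL)
    if tm:
        for entry in tm.group(1).split(","):
            parts = entry.split()
            if len(parts) == 2:
                translate[parts[0]] = parts[1].strip("'")
            elif parts:
                raise PhyloError(f"malformed TRANSLATE entry: {entry.strip()!r}")
    trees = TreeList()
    for tmatch in re.finditer(
        r"\btree\s+[^=]+=\s*(?:\[[^\]]*\]\s*)?([^;]+;)", block, re.IGNORECASE
    ):
        tree = parse_newick(tmatch.group(1))
        if translate:
            for tip in tree.tips():
                if tip.label in translate:
                    tip.label = translate[tip.label]
            tree.validate()
        trees.append(tree)
    return trees


def read_trees(stream: Union[str, bytes, IO], format: str = "newick") -> TreeList:
    """Read all trees from a stream/string in ``newick`` or ``nexus`` format.

    Newick files hold one statement per ``;``; gzip-compressed input is
    decompressed transparently (magic-byte detection).
    """
    text = _decode_stream(stream)
    if format == "newick":
        return TreeList(
            parse_newick(stmt) for stmt in _iter_newick_statements(text)
        )
    if format == "nexus":
        return _parse_nexus_trees(text)
    raise PhyloError(f"unknown tree format: {format!r}")


def write_trees(trees: TreeList, format: str = "newick") -> str:
    """Serialize a TreeList in ``newick`` (one per line) or ``nexus``."""
    if format == "newick":
        return "".join(write_newick(t) + "\n" for t in trees)
    if format == "nexus":
        lines = ["#NEXUS", "BEGIN TREES;"]
        for i, tree in enumerate(trees, 1):
            lines.append(f"  TREE tree{i} = {write_newick(tree)}")
        lines.append("END;")
        return "\n".join(lines) + "\n"
    raise PhyloError(f"unknown tree format: {format!r}")


def read_trees_path(path: str, format: str = "newick") -> TreeList:
    with open(path, "rb") as fh:
        return read_trees(fh, format)
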