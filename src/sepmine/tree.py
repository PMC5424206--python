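"""Minimal rooted-representation phylogenetic tree.

The maximum-likelihood engine needs a mutable tree with branch lengths and
integer bootstrap supports on internal nodes.  Trees are stored rooted (a
root node with children) but compared as unrooted objects through their
bipartition (split) sets, which is the standard convention for unrooted ML
trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass
class Node:
    name: str | None = None
    length: float | None = None
    support: int | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def traverse_preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def traverse_postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))


class Tree:
    """A tree with labeled leaves, branch lengths and optional supports."""

    def __init__(self, root: Node):
        self.root = root

    # -- queries ---------------------------------------------------------

    def leaves(self) -> list[Node]:
        return [n for n in self.root.traverse_postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name or "" for n in self.leaves()]

    def splits(self) -> set[frozenset[frozenset[str]]]:
        """Nontrivial bipartitions of the leaf set, unrooted convention.

        Each split is a frozenset of the two leaf-name sides, so the
        representation is invariant to rooting.
        """
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset[frozenset[str]]] = set()
        for node in self.root.traverse_postorder():
            if node.is_leaf or node.parent is None:
                continue
            side = frozenset(
                leaf.name for leaf in node.traverse_postorder() if leaf.is_leaf
            )
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset((side, other)))
        return out

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            new = Node(name=node.name, length=node.length, support=node.support)
            for child in node.children:
                new.add(_copy(child))
            return new

        return Tree(_copy(self.root))

    # -- serialization ---------------------------------------------------

    def to_newick(self) -> str:
        return format_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.to_newick()})"


def format_newick(tree: Tree) -> str:
    """Serialize to Newick; internal supports are written as node labels."""

    def _fmt(node: Node) -> str:
        if node.is_leaf:
            if not node.name:
                raise ValueError("unlabeled leaf cannot be serialized")
            label = node.name
        else:
            inner = ",".join(_fmt(c) for c in node.children)
            label = f"({inner})"
            if node.support is not None:
                label += str(int(node.support))
        if node.length is not None:
            label += f":{node.length:.10g}"
        return label

    return _fmt(tree.root) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a Newick string with branch lengths and integer supports."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def _error(msg: str) -> ValueError:
        return ValueError(f"Newick parse error at position {pos}: {msg}")

    def _parse_label() -> tuple[str, float | None]:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        token = s[start:pos]
        if ":" in token:  # cannot happen: ':' is a terminator
            raise _error("unexpected ':'")
        length = None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            lstart = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            length = float(s[lstart:pos])
        return token, length

    def _parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add(_parse_node())
                if pos >= len(s):
                    raise _error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise _error(f"unexpected character {s[pos]!r}")
            label, length = _parse_label()
            if label:
                node.support = int(float(label))
            node.length = length
        else:
            label, length = _parse_label()
            if not label:
                raise _error("leaf without a name")
            node.name = label
            node.length = length
        return node

    root = _parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick string: {s[pos:]!r}")
    return Tree(root)
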