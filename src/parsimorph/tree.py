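"""A small rooted-tree container with unrooted comparison helpers.

Trees here are stored rooted (a root node with children), but most of
the phylogenetic machinery treats them as unrooted: two trees are the
same unrooted topology when they share a leaf set and the same set of
nontrivial bipartitions.  Polytomies are allowed everywhere.
"""

from __future__ import annotations

from typing import Callable, Iterator

from .matrix import _norm_label


class Node:
    __slots__ = ("label", "children", "parent", "length", "value", "bin", "meta")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.value: float | None = None  # continuous trait slot
        self.bin: int | None = None
        self.meta: dict = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Node {self.label or '*'} deg={len(self.children)}>"


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- construction ---------------------------------------------------
    @classmethod
    def from_nested(cls, spec) -> "Tree":
        """Build from nested tuples/lists of leaf labels, e.g.
        ``(("A", "B"), ("C", "D"))``."""

        def build(obj) -> Node:
            if isinstance(obj, (tuple, list)):
                node = Node()
                for sub in obj:
                    node.add(build(sub))
                return node
            return Node(label=str(obj))

        return cls(build(spec))

    # -- traversal ------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def nodes(self) -> list[Node]:
        return list(self.postorder())

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label or "" for n in self.leaves()]

    # -- topology -------------------------------------------------------
    def leaf_set(self) -> frozenset[str]:
        return frozenset(_norm_label(lbl) for lbl in self.leaf_labels())

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Nontrivial unrooted splits, each encoded as the side that does
        not contain the lexicographically smallest leaf label."""
        all_leaves = self.leaf_set()
        if len(all_leaves) < 4:
            return frozenset()
        ref = min(all_leaves)
        below: dict[int, frozenset[str]] = {}
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset({_norm_label(node.label or "")})
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                side = s if ref not in s else all_leaves - s
                if 2 <= len(side) <= len(all_leaves) - 2:
                    splits.add(side)
        return frozenset(splits)

    def clades(self) -> frozenset[frozenset[str]]:
        """Rooted clades (leaf sets below each internal node, root included)."""
        below: dict[int, frozenset[str]] = {}
        out: set[frozenset[str]] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset({_norm_label(node.label or "")})
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                out.add(s)
        return frozenset(out)

    def same_unrooted(self, other: "Tree") -> bool:
        return (
            self.leaf_set() == other.leaf_set()
            and self.bipartitions() == other.bipartitions()
        )

    def topology_key(self) -> tuple:
        """Hashable unrooted-topology identity (leaf set + splits)."""
        return (self.leaf_set(), self.bipartitions())

    # -- editing --------------------------------------------------------
    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.value, new.bin = node.value, node.bin
            new.meta = dict(node.meta)
            for child in node.children:
                new.add(clone(child))
            return new

        return Tree(clone(self.root))

    def suppress_unifurcations(self) -> "Tree":
        """Remove internal nodes with a single child (in place)."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if not node.is_leaf and len(node.children) == 1:
                    (child,) = node.children
                    if node.parent is None:
                        child.parent = None
                        self.root = child
                    else:
                        parent = node.parent
                        idx = parent.children.index(node)
                        parent.children[idx] = child
                        child.parent = parent
                    changed = True
        return self

    # -- serialisation ---------------------------------------------------
    def to_newick(
        self,
        include_lengths: bool = True,
        annotate: Callable[[Node], str] | None = None,
    ) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = (node.label or "").replace(" ", "_")
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    s += str(node.label).replace(" ", "_")
            if annotate is not None:
                note = annotate(node)
                if note:
                    s += f"[&{note}]"
            if include_lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Tree {len(self.leaf_labels())} leaves>"
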