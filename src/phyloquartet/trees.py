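"""Phylogenetic trees: a light node-link structure with dendropy-backed
newick I/O.

Branch lengths live on the child end of each edge.  Unrooted trees are
represented rooted at an arbitrary internal node with >=3 children and a
``rooted=False`` flag; under reversible models the likelihood does not
depend on that choice.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy
import numpy as np


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Tree of :class:`Node` objects with unique leaf labels."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for n in self.postorder():
            if n is not self.root and n.length is not None:
                if not np.isfinite(n.length) or n.length < 0:
                    raise ValueError("branch lengths must be finite and nonnegative")

    # -- I/O ------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True,
                                   suppress_internal_node_taxa=True)
        except Exception as exc:
            raise ValueError(f"unparseable newick: {exc}") from exc
        rooted_flag = dt.is_rooted if rooted is None else rooted

        def convert(dn) -> Node:
            if dn.is_leaf():
                lab = dn.taxon.label if dn.taxon is not None else dn.label
            else:
                lab = dn.label
            node = Node(lab, dn.edge.length)
            for c in dn.child_nodes():
                node.add(convert(c))
            return node

        return cls(convert(dt.seed_node), rooted=bool(rooted_flag))

    def to_newick(self, decimals: int | None = None) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{decimals}f}" if decimals is not None else repr(float(x))

        def write(n: Node) -> str:
            if n.is_leaf:
                s = _quote(n.label or "")
            else:
                s = "(" + ",".join(write(c) for c in n.children) + ")"
                if n.label:
                    s += _quote(n.label)
            if n.length is not None and n is not self.root:
                s += ":" + fmt(n.length)
            return s

        out = write(self.root) + ";"
        # round-trip through dendropy to guarantee parseable output
        dendropy.Tree.get(data=out, schema="newick", preserve_underscores=True)
        return out

    # -- traversal ------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        def walk(n: Node):
            for c in n.children:
                yield from walk(c)
            yield n
        return walk(self.root)

    def preorder(self) -> Iterator[Node]:
        def walk(n: Node):
            yield n
            for c in n.children:
                yield from walk(c)
        return walk(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(f"no leaf named {label!r}")

    def copy(self) -> "PhyloTree":
        def dup(n: Node) -> Node:
            m = Node(n.label, n.length)
            for c in n.children:
                m.add(dup(c))
            return m
        return PhyloTree(dup(self.root), rooted=self.rooted)

    # -- surgery --------------------------------------------------------
    def suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for n in list(self.postorder()):
                if n is self.root and len(n.children) == 1:
                    child = n.children[0]
                    child.parent = None
                    child.length = None
                    self.root = child
                    changed = True
                elif n is not self.root and len(n.children) == 1:
                    child = n.children[0]
                    child.length = (child.length or 0.0) + (n.length or 0.0)
                    parent = n.parent
                    parent.children[parent.children.index(n)] = child
                    child.parent = parent
                    changed = True

    def prune_leaf(self, label: str) -> None:
        leaf = self.find_leaf(label)
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot prune the root")
        parent.children.remove(leaf)
        self.suppress_unifurcations()

    def reroot_at(self, node: Node) -> "PhyloTree":
        """Return a copy rerooted at (an internal) node; lengths preserved."""
        # work on the original structure non-destructively via parent chains
        if node.is_leaf:
            raise ValueError("reroot target must be internal")

        def rebuild(n: Node, come_from: Node | None, length: float | None) -> Node:
            m = Node(n.label, length)
            neighbors: list[tuple[Node, float | None]] = []
            for c in n.children:
                if c is not come_from:
                    neighbors.append((c, c.length))
            if n.parent is not None and n.parent is not come_from:
                neighbors.append((n.parent, n.length))
            for nb, ln in neighbors:
                m.add(rebuild(nb, n, ln))
            return m

        return PhyloTree(rebuild(node, None, None), rooted=self.rooted)

    # -- bipartitions ----------------------------------------------------
    def edge_bipartitions(self) -> list[tuple[Node, frozenset[str], frozenset[str]]]:
        """(child_node, below_set, above_set) for every non-root edge."""
        all_leaves = frozenset(self.leaf_labels())
        out = []
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            if n is not self.root:
                out.append((n, below[id(n)], all_leaves - below[id(n)]))
        return out

    def edge_id(self, below: frozenset[str], above: frozenset[str]) -> str:
        side = min(sorted(below), sorted(above))
        return "|".join(side)

    def __repr__(self) -> str:
        return f"PhyloTree({self.n_leaves} leaves, rooted={self.rooted})"


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def quartet_tree(labels: Iterable[str], lengths: Iterable[float]) -> PhyloTree:
    """Unrooted quartet (a,b|c,d): edges (ta, tb, internal, tc, td)."""
    a, b, c, d = labels
    ta, tb, ti, tc, td = lengths
    root = Node()
    root.add(Node(a, ta))
    root.add(Node(b, tb))
    inner = root.add(Node(None, ti))
    inner.add(Node(c, tc))
    inner.add(Node(d, td))
    return PhyloTree(root, rooted=False)


def random_tree(
    labels: list[str],
    rng: np.random.Generator,
    branch_low: float = 0.02,
    branch_high: float = 0.5,
) -> PhyloTree:
    """Random binary topology via sequential joining, uniform branch lengths.

    The root trifurcates (unrooted convention) when four or more labels are
    given.
    """
    nodes = [Node(lab) for lab in labels]
    stop = 3 if len(labels) >= 4 else 2
    while len(nodes) > stop:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        for k in (j, i):
            child = nodes.pop(k)
            parent.add(child)
        nodes.append(parent)
    root = Node()
    for child in nodes:
        root.add(child)
    tree = PhyloTree(root, rooted=len(labels) < 4)
    for n in tree.postorder():
        if n is not tree.root:
            n.length = float(rng.uniform(branch_low, branch_high))
    return tree
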