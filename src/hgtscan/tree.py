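"""Rooted gene trees carrying per-edge bootstrap supports.

Trees arrive as newick in the RAxML dialect: integer bootstrap supports
(0-100) stored as internal *node labels*, branch lengths in
substitutions/site.  Parsing is delegated to dendropy; the sister-group and
rerooting logic runs on the lightweight :class:`Node` structure below, where
a support value is an attribute of the edge between a node and its parent.
Rerooting therefore keeps each support attached to the bipartition it
measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import dendropy

from .errors import FormatError, ValidationError

__all__ = ["Node", "SupportTree", "parse_newick_with_support"]


@dataclass
class Node:
    """One node of a rooted tree; ``length``/``support`` describe the edge
    to its parent (``None`` at the root or where absent)."""

    name: str | None = None
    length: float | None = None
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tip_labels(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_tip]

    def copy(self) -> "Node":
        return Node(
            self.name,
            self.length,
            self.support,
            [c.copy() for c in self.children],
        )


def _format_length(x: float | None) -> str:
    return "" if x is None else f":{x:g}"


def _to_newick(node: Node) -> str:
    if node.is_tip:
        return f"{node.name}{_format_length(node.length)}"
    inner = ",".join(_to_newick(c) for c in node.children)
    label = "" if node.support is None else str(node.support)
    return f"({inner}){label}{_format_length(node.length)}"


class SupportTree:
    """A gene tree with unique tip labels, branch lengths, supports, and a
    tip-to-genome map."""

    def __init__(self, root: Node, tip_genome: Mapping[str, str]):
        labels = root.tip_labels()
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate tip labels in tree")
        missing = [t for t in labels if t not in tip_genome]
        if missing:
            raise ValidationError(f"tips missing from tip_genome map: {missing}")
        for n in root.walk():
            if n.length is not None and n.length < 0:
                raise ValidationError(f"negative branch length {n.length}")
            if n.support is not None and not 0 <= n.support <= 100:
                raise ValidationError(f"support {n.support} outside [0, 100]")
        self.root = root
        self.tip_genome = {t: tip_genome[t] for t in labels}

    # -- basic accessors ---------------------------------------------------

    def tips(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return self.root.tip_labels()

    def find_tip(self, label: str) -> Node:
        for n in self.root.walk():
            if n.is_tip and n.name == label:
                return n
        raise ValidationError(f"tip {label!r} not in tree")

    def parents(self) -> dict[int, Node]:
        """Map ``id(child) -> parent`` for the current topology."""
        out: dict[int, Node] = {}
        for n in self.root.walk():
            for c in n.children:
                out[id(c)] = n
        return out

    def genomes(self) -> set[str]:
        return set(self.tip_genome.values())

    def copy(self) -> "SupportTree":
        return SupportTree(self.root.copy(), dict(self.tip_genome))

    def newick(self) -> str:
        return _to_newick(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SupportTree({self.newick()})"

    # -- rerooting ---------------------------------------------------------

    def root_on_outgroup(self, outgroup_genome: str) -> tuple["SupportTree", bool]:
        """Root on the edge subtending the smallest clade holding every
        outgroup tip.

        Returns ``(rooted_tree, outgroup_conflict)``.  When the outgroup
        tips are not monophyletic in the unrooted topology, the root goes on
        the edge subtending the largest pure-outgroup clade and the tree is
        flagged as an outgroup conflict.
        """
        out_tips = {t for t, g in self.tip_genome.items() if g == outgroup_genome}
        if not out_tips:
            raise ValidationError(f"no {outgroup_genome} tip present for rooting")
        all_tips = set(self.tip_labels())

        # Already rooted this way: binary root with one child holding
        # exactly the outgroup tips.
        if len(self.root.children) == 2:
            for child in self.root.children:
                if set(child.tip_labels()) == out_tips:
                    return self.copy(), False

        graph = _Graph.from_rooted(self.root)
        graph.suppress_degree_two()
        edge, conflict = graph.outgroup_edge(out_tips, all_tips)
        root = graph.build_rooted(edge)
        return SupportTree(root, self.tip_genome), conflict


# ---------------------------------------------------------------------------
# Undirected edge graph used only for rerooting.


class _GNode:
    __slots__ = ("name", "edges")

    def __init__(self, name: str | None):
        self.name = name
        self.edges: list[_GEdge] = []


class _GEdge:
    __slots__ = ("a", "b", "length", "support")

    def __init__(self, a: _GNode, b: _GNode, length: float | None, support: int | None):
        self.a, self.b, self.length, self.support = a, b, length, support

    def other(self, n: _GNode) -> _GNode:
        return self.b if n is self.a else self.a


class _Graph:
    def __init__(self) -> None:
        self.nodes: list[_GNode] = []
        self.edges: list[_GEdge] = []

    @classmethod
    def from_rooted(cls, root: Node) -> "_Graph":
        g = cls()

        def add(node: Node) -> _GNode:
            gn = _GNode(node.name if node.is_tip else None)
            g.nodes.append(gn)
            for c in node.children:
                gc = add(c)
                e = _GEdge(gn, gc, c.length, c.support)
                g.edges.append(e)
                gn.edges.append(e)
                gc.edges.append(e)
            return gn

        add(root)
        return g

    def suppress_degree_two(self) -> None:
        """Merge the two edges at any unlabelled degree-2 node (e.g. the
        basal node of a rooted binary newick) into one edge."""
        changed = True
        while changed:
            changed = False
            for n in self.nodes:
                if n.name is None and len(n.edges) == 2:
                    e1, e2 = n.edges
                    a, b = e1.other(n), e2.other(n)
                    length = None
                    if e1.length is not None or e2.length is not None:
                        length = (e1.length or 0.0) + (e2.length or 0.0)
                    support = e1.support if e1.support is not None else e2.support
                    merged = _GEdge(a, b, length, support)
                    for e, side in ((e1, a), (e2, b)):
                        side.edges.remove(e)
                        self.edges.remove(e)
                    a.edges.append(merged)
                    b.edges.append(merged)
                    self.edges.append(merged)
                    self.nodes.remove(n)
                    changed = True
                    break

    def _side_tips(self, edge: _GEdge, start: _GNode) -> set[str]:
        """Tip names reachable from ``start`` without crossing ``edge``."""
        seen: set[int] = {id(start)}
        out: set[str] = set()
        stack = [start]
        while stack:
            n = stack.pop()
            if n.name is not None:
                out.add(n.name)
            for e in n.edges:
                if e is edge:
                    continue
                m = e.other(n)
                if id(m) not in seen:
                    seen.add(id(m))
                    stack.append(m)
        return out

    def outgroup_edge(
        self, out_tips: set[str], all_tips: set[str]
    ) -> tuple[_GEdge, bool]:
        best: _GEdge | None = None
        best_count = -1
        for edge in self.edges:
            for side in (edge.a, edge.b):
                tips = self._side_tips(edge, side)
                if tips == out_tips:
                    return edge, False
                if tips and tips <= out_tips and len(tips) > best_count:
                    best, best_count = edge, len(tips)
        assert best is not None  # every outgroup tip's own edge qualifies
        return best, True

    def build_rooted(self, edge: _GEdge) -> Node:
        """Build a rooted tree with the root bisecting ``edge``; the edge's
        support (one bipartition) is carried on both root children."""
        half = None if edge.length is None else edge.length / 2.0

        def grow(n: _GNode, came: _GEdge) -> Node:
            node = Node(name=n.name, length=came.length, support=came.support)
            for e in n.edges:
                if e is came:
                    continue
                node.children.append(grow(e.other(n), e))
            # order-stable output: tips before clades, then by first tip label
            node.children.sort(key=lambda c: (not c.is_tip, c.tip_labels()[0]))
            return node

        left = grow(edge.a, edge)
        right = grow(edge.b, edge)
        for child in (left, right):
            child.length = half
            child.support = edge.support
        root = Node(children=sorted(
            (left, right), key=lambda c: (not c.is_tip, c.tip_labels()[0])
        ))
        return root


# ---------------------------------------------------------------------------
# Parsing


def parse_newick_with_support(
    text: str, tip_genome: Mapping[str, str]
) -> SupportTree:
    """Parse newick with integer internal-node labels as bootstrap supports.

    Supports become attributes of the edge above each labelled node;
    unlabelled internal edges carry no support.  Raises
    :class:`FormatError` on syntax errors and :class:`ValidationError` on
    out-of-range supports or tips absent from ``tip_genome``.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise FormatError("unlabelled tip in newick")
            return Node(name=dnode.taxon.label, length=dnode.edge.length)
        support: int | None = None
        if dnode.label is not None and dnode.label != "":
            try:
                support = int(dnode.label)
            except ValueError as exc:
                raise ValidationError(
                    f"internal node label {dnode.label!r} is not an integer "
                    "bootstrap support"
                ) from exc
            if not 0 <= support <= 100:
                raise ValidationError(f"support {support} outside [0, 100]")
        node = Node(length=dnode.edge.length, support=support)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.support = None  # a root label is not an edge support
    return SupportTree(root, tip_genome)
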