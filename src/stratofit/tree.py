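"""Rooted trees with named tips, polytomies allowed.

The tree type here is deliberately small: parent/child links, labels, and a
free-form ``annotations`` dict per node that downstream modules use to attach
minimum ages (Ma) and ancestral-area distributions.  Parsing and writing go
through dendropy, which handles quoting, comments and branch lengths; branch
lengths are discarded on input because every age in this package derives
from fossil occurrence data, not from the cladogram.
"""

from __future__ import annotations

import logging
import re
from typing import Callable, Iterable, Iterator, Optional

import dendropy

from .errors import TreeParseError

log = logging.getLogger(__name__)

__all__ = ["Node", "Tree", "parse_newick", "write_newick", "normalize_label"]


def normalize_label(label: str) -> str:
    """Normalize a taxon label: trim, collapse whitespace runs to a single
    underscore (Newick convention: ``"A b" == "A_b"``)."""
    return re.sub(r"\s+", "_", label.strip())


class Node:
    """One node of a rooted tree.  Tips carry a taxon label; internal nodes
    may carry an optional clade label."""

    __slots__ = ("label", "parent", "children", "annotations")

    def __init__(self, label: Optional[str] = None):
        self.label = label
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.annotations: dict = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> Iterator["Node"]:
        return (n for n in self.postorder() if n.is_leaf)

    def tip_labels(self) -> frozenset[str]:
        return frozenset(leaf.label for leaf in self.leaves())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '(internal)'}>"


class Tree:
    """A rooted tree; polytomies allowed, child order meaningful."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return list(self.root.leaves())

    def tip_labels(self) -> frozenset[str]:
        return self.root.tip_labels()

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.root.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    # -- node identity -----------------------------------------------------
    def node_id(self, node: Node) -> str:
        """Stable human-readable id: the tip label for leaves, the clade
        label for labelled internal nodes, else ``NodeK`` by postorder rank."""
        if node.is_leaf:
            return node.label
        if node.label:
            return node.label
        for k, n in enumerate(self.postorder()):
            if n is node:
                return f"Node{k}"
        raise ValueError("node not in tree")

    def node_ids(self) -> dict[Node, str]:
        ids = {}
        for k, n in enumerate(self.postorder()):
            if n.is_leaf or n.label:
                ids[n] = n.label
            else:
                ids[n] = f"Node{k}"
        return ids

    def find_tip(self, label: str) -> Node:
        label = normalize_label(label)
        for leaf in self.root.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(f"tip {label!r} not in tree")

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of a set of tip labels."""
        want = {normalize_label(l) for l in labels}
        missing = want - self.tip_labels()
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        for node in self.postorder():
            if not node.is_leaf or node.label in want:
                if want <= node.tip_labels():
                    return node
        return self.root

    # -- editing -----------------------------------------------------------
    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label)
            new.annotations = dict(node.annotations)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def prune_to(self, keep: Iterable[str],
                 on_drop: Optional[Callable[[str], None]] = None) -> "Tree":
        """Return a copy restricted to the tips in *keep*; unary nodes left
        by the removal are collapsed so internal nodes keep >= 2 children.
        The rooted topology restricted to surviving tips is unchanged."""
        keep = {normalize_label(l) for l in keep}

        def build(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.label in keep:
                    new = Node(node.label)
                    new.annotations = dict(node.annotations)
                    return new
                if on_drop is not None:
                    on_drop(node.label)
                return None
            kids = [build(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            new = Node(node.label)
            new.annotations = dict(node.annotations)
            for k in kids:
                new.add_child(k)
            return new

        root = build(self.root)
        if root is None:
            raise TreeParseError("pruning removed every tip")
        return Tree(root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree n_tips={self.n_tips}>"


def _validate_and_collapse(tree: Tree) -> Tree:
    """Enforce Tree invariants after parsing: unique non-empty tip labels,
    unary internal nodes collapsed."""
    seen: set[str] = set()
    for leaf in tree.leaves():
        if not leaf.label:
            raise TreeParseError("tip with empty label")
        if leaf.label in seen:
            raise TreeParseError(f"duplicate tip label {leaf.label!r}")
        seen.add(leaf.label)
    if not seen:
        raise TreeParseError("empty tree")

    # collapse unary chains (can arise from input like "((A));")
    def collapse(node: Node) -> Node:
        while len(node.children) == 1:
            child = node.children[0]
            child.label = child.label or node.label
            node = child
        node.children = [collapse(c) for c in node.children]
        for c in node.children:
            c.parent = node
        return node

    root = collapse(tree.root)
    root.parent = None
    return Tree(root)


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    had_lengths = False

    def build(dnode) -> Node:
        nonlocal had_lengths
        if dnode.edge.length is not None:
            had_lengths = True
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(normalize_label(label) if label else None)
        else:
            label = dnode.label or (dnode.taxon.label if dnode.taxon else None)
            node = Node(normalize_label(label) if label else None)
        for dchild in dnode.child_nodes():
            node.add_child(build(dchild))
        return node

    root = build(dtree.seed_node)
    if had_lengths:
        log.info("branch lengths present in input tree; ignored "
                 "(ages derive from occurrence data)")
    return _validate_and_collapse(Tree(root))


def parse_newick(text: str) -> Tree:
    """Parse a single rooted Newick tree.

    Polytomies and child order are preserved; quoted labels are accepted;
    branch lengths and internal support values are tolerated and ignored.
    Raises :class:`TreeParseError` for malformed input, duplicate or empty
    tip labels, or an empty tree.
    """
    if not text or not text.strip():
        raise TreeParseError("empty tree string")
    # cheap structural check so the error can name a position
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise TreeParseError(f"unbalanced parentheses ({depth} unclosed '(')")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeParseError(f"could not parse Newick: {exc}") from exc
    return _from_dendropy(dtree)


def _quote_if_needed(label: str) -> str:
    if re.search(r"[\s()\[\]{}:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Serialize to Newick; round-trips through :func:`parse_newick` to an
    isomorphic tree (same tip set under every node, child order kept)."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return _quote_if_needed(node.label)
        inner = ",".join(fmt(c) for c in node.children)
        label = _quote_if_needed(node.label) if node.label else ""
        return f"({inner}){label}"

    return fmt(tree.root) + ";"
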