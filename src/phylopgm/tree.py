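"""Rooted species phylogenies: parsing, rerooting and edge enumeration.

The aggregation model consumes a tree rerooted so that the focal species
(typically human) sits at the root: the class label lives at the root and
evidence flows along parent->child edges.  This module keeps trees as a
light parent-map structure -- Newick parsing is delegated to dendropy,
while rerooting and serialization are implemented directly because the
rerooting convention (suppress a degree-2 old root, sum its two branch
lengths) must match the per-edge probability tables exactly.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterator, List, Sequence, Tuple

import dendropy

__all__ = [
    "PhyloTree",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "reroot_at",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree violates structural invariants (duplicate names, cycles...)."""


class PhyloTree:
    """A rooted tree with branch lengths and a stable child order.

    Parameters
    ----------
    root:
        Name of the root node.
    children_of:
        Mapping node -> ordered sequence of child names.  Nodes without an
        entry are leaves.
    branch_length:
        Mapping child -> length of the edge above it (>= 0).  Every
        non-root node must have an entry.
    """

    __slots__ = ("root", "_children", "_blen")

    def __init__(
        self,
        root: str,
        children_of: Dict[str, Sequence[str]],
        branch_length: Dict[str, float],
    ) -> None:
        self.root = root
        self._children: Dict[str, Tuple[str, ...]] = {
            n: tuple(ch) for n, ch in children_of.items() if ch
        }
        self._blen: Dict[str, float] = dict(branch_length)
        self._validate()

    def _validate(self) -> None:
        seen_children: set[str] = set()
        for parent, kids in self._children.items():
            for c in kids:
                if c in seen_children:
                    raise TreeValidationError(f"node {c!r} has more than one parent")
                seen_children.add(c)
        if self.root in seen_children:
            raise TreeValidationError(f"root {self.root!r} must not have a parent")
        # connectivity + acyclicity: preorder walk from the root must reach
        # every node mentioned anywhere, exactly once
        reached = set(self.preorder())
        mentioned = {self.root} | seen_children | set(self._children)
        if reached != mentioned:
            raise TreeValidationError(
                f"tree is not connected: unreachable nodes {sorted(mentioned - reached)}"
            )
        if len(reached) != len(mentioned):  # pragma: no cover - defensive
            raise TreeValidationError("duplicate node identifiers")
        for child in seen_children:
            if child not in self._blen:
                raise TreeValidationError(f"missing branch length for node {child!r}")
            if self._blen[child] < 0:
                raise TreeValidationError(
                    f"negative branch length {self._blen[child]} on node {child!r}"
                )

    # -- structure accessors ------------------------------------------------

    @property
    def nodes(self) -> set:
        return set(self.preorder())

    @property
    def n_nodes(self) -> int:
        return len(list(self.preorder()))

    @property
    def parent_of(self) -> Dict[str, str]:
        return {c: p for p, kids in self._children.items() for c in kids}

    @property
    def branch_length(self) -> Dict[str, float]:
        return dict(self._blen)

    def children(self, node: str) -> Tuple[str, ...]:
        return self._children.get(node, ())

    def is_leaf(self, node: str) -> bool:
        return node not in self._children

    @property
    def leaf_names(self) -> List[str]:
        return [n for n in self.preorder() if self.is_leaf(n)]

    def preorder(self) -> Iterator[str]:
        """Yield node names in deterministic preorder (root first)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self._children.get(node, ())))

    def edges(self) -> List[Tuple[str, str, float]]:
        """All (parent, child, length) triples in preorder of the child."""
        return [
            (self.parent_of[n], n, self._blen[n])
            for n in self.preorder()
            if n != self.root
        ]

    # -- distances ----------------------------------------------------------

    def distance(self, a: str, b: str) -> float:
        """Path length between two nodes, summing branch lengths."""
        parent = self.parent_of
        anc_a: Dict[str, float] = {a: 0.0}
        node, d = a, 0.0
        while node != self.root:
            d += self._blen[node]
            node = parent[node]
            anc_a[node] = d
        node, d = b, 0.0
        while True:
            if node in anc_a:
                return d + anc_a[node]
            d += self._blen[node]
            node = parent[node]

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        def rec(node: str) -> str:
            kids = self._children.get(node, ())
            inner = f"({','.join(rec(c) for c in kids)})" if kids else ""
            label = f"{inner}{node}"
            if node != self.root:
                label += f":{self._blen[node]:.10g}"
            return label

        return rec(self.root) + ";"

    def __repr__(self) -> str:
        return (
            f"PhyloTree(root={self.root!r}, n_nodes={self.n_nodes}, "
            f"n_leaves={len(self.leaf_names)})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return (
            self.root == other.root
            and self._children == other._children
            and self._blen == other._blen
        )


def parse_newick(text: str, default_branch_length: float = 0.0) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Unnamed internal nodes receive deterministic names ``_internal_<i>``
    where ``i`` is the node's preorder index.  Branch lengths absent from
    the source default to ``default_branch_length`` (0.0) with a warning;
    the aggregation model only uses lengths implicitly (one conditional
    table per edge), so a missing length is non-fatal.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from None
    if dtree.seed_node is None or (
        dtree.seed_node.taxon is None
        and dtree.seed_node.label is None
        and not dtree.seed_node.child_nodes()
    ):
        raise NewickParseError("malformed Newick: empty tree")

    names: Dict[int, str] = {}
    missing_lengths: List[str] = []
    for i, node in enumerate(dtree.preorder_node_iter()):
        if node.taxon is not None and node.taxon.label:
            name = str(node.taxon.label)
        elif node.label:
            name = str(node.label)
        else:
            name = f"_internal_{i}"
        names[id(node)] = name

    seen: set[str] = set()
    for name in names.values():
        if name in seen:
            raise TreeValidationError(f"duplicate node name {name!r}")
        seen.add(name)

    children_of: Dict[str, List[str]] = {}
    branch_length: Dict[str, float] = {}
    root = names[id(dtree.seed_node)]
    for node in dtree.preorder_node_iter():
        name = names[id(node)]
        kids = node.child_nodes()
        if kids:
            children_of[name] = [names[id(k)] for k in kids]
        if node is not dtree.seed_node:
            length = node.edge.length
            if length is None:
                missing_lengths.append(name)
                length = default_branch_length
            branch_length[name] = float(length)
    if missing_lengths:
        warnings.warn(
            f"{len(missing_lengths)} branch length(s) missing in Newick source; "
            f"defaulting to {default_branch_length} for {missing_lengths[:5]}...",
            stacklevel=2,
        )
    return PhyloTree(root, children_of, branch_length)


def reroot_at(tree: PhyloTree, focal: str) -> PhyloTree:
    """Return a tree rerooted so that ``focal`` becomes the root.

    Parent--child orientations along the path from the old root to the
    focal node are reversed with branch lengths preserved.  If the old
    root is left with degree 2 it is suppressed and its two incident
    branch lengths summed, so no artifactual edge splits a lineage.  The
    leaf-to-leaf path-length matrix is invariant under this operation.
    """
    if focal not in tree.nodes:
        raise KeyError(f"focal node {focal!r} not in tree")
    if focal == tree.root:
        return tree

    parent = tree.parent_of
    path = [focal]
    while path[-1] != tree.root:
        path.append(parent[path[-1]])

    children: Dict[str, List[str]] = {
        n: list(tree.children(n)) for n in tree.preorder() if tree.children(n)
    }
    blen = tree.branch_length

    # reverse each edge on the focal->root path; the reversed edge keeps
    # the original length (which was keyed by the original child)
    for child, par in zip(path, path[1:]):
        children[par].remove(child)
        children.setdefault(child, []).append(par)
        blen[par] = tree.branch_length[child]
    del blen[focal]

    old_root = path[-1]
    if len(children.get(old_root, ())) == 1:
        # degree-2 node after rerooting: one remaining child + new parent
        (only_child,) = children.pop(old_root)
        new_parent = path[-2]
        idx = children[new_parent].index(old_root)
        children[new_parent][idx] = only_child
        blen[only_child] = blen[only_child] + blen.pop(old_root)

    return PhyloTree(focal, children, blen)
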