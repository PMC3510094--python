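"""Newick I/O and the tree containers used throughout the package.

Two kinds of trees appear in a pacemaker analysis:

* a rooted, strictly binary **supertree** over the full taxon set, whose
  2m-2 edge lengths are the free parameters of the pacemaker models, and
* a forest of **gene trees**: unrooted binary trees (internal nodes of
  degree 3) over subsets of the supertree taxa, with branch lengths in
  substitutions per site.

Parsing and serialisation go through dendropy; the classes here are thin,
algorithm-friendly wrappers that add the two things the downstream fit
needs and a general tree library does not provide: stable edge identities
that survive serialisation, and leaf-set restriction that records which
original supertree edges compose each collapsed edge.

Edge identity conventions: a supertree edge is identified by the clade
below it, serialised as a dense integer id assigned in a canonical
traversal (children ordered by smallest descendant label, postorder).
An unrooted gene-tree edge is identified by its leaf bipartition,
canonicalised as the side not containing the lexicographically smallest
leaf.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "NewickError",
    "ValidationError",
    "Node",
    "SuperTree",
    "GeneTree",
    "read_newick_tree",
    "read_forest",
    "write_forest",
    "read_taxon_set",
    "restrict_tree",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class ValidationError(ValueError):
    """Structurally valid tree that violates a forest-level invariant."""


class Node:
    """A tree node; an edge is the (parent, self) link with ``self.length``."""

    __slots__ = ("label", "length", "children", "edge_id")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = []
        self.edge_id: int | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(v.children)
        return reversed(out)

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(v.label for v in self.postorder() if v.is_leaf())

    def copy(self) -> "Node":
        c = Node(self.label, self.length)
        c.edge_id = self.edge_id
        c.children = [k.copy() for k in self.children]
        return c

    def _min_leaf(self) -> str:
        return min(v.label for v in self.postorder() if v.is_leaf())

    def sort_canonical(self) -> None:
        """Order children everywhere by smallest descendant label (in place)."""
        for v in self.postorder():
            v.children.sort(key=Node._min_leaf)

    def newick(self, lengths: bool = True, precision: int = 17) -> str:
        parts = []

        def rec(v: Node) -> None:
            if v.children:
                parts.append("(")
                for i, c in enumerate(v.children):
                    if i:
                        parts.append(",")
                    rec(c)
                parts.append(")")
            if v.label is not None:
                parts.append(_quote_label(v.label))
            if lengths and v is not self:
                parts.append(f":{v.length:.{precision}g}")

        rec(self)
        parts.append(";")
        return "".join(parts)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# dendropy bridge


def _from_dendropy(dtree: dendropy.Tree) -> Node:
    def conv(dnode) -> Node:
        label = None
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise ValidationError("leaf without a label")
            label = dnode.taxon.label
        n = Node(label, dnode.edge.length if dnode.edge.length is not None else 0.0)
        n.children = [conv(c) for c in dnode.child_nodes()]
        return n

    return conv(dtree.seed_node)


def _parse_newick(text: str) -> Node:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "same taxa" in str(exc) or "duplicate" in str(exc).lower():
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        raise NewickError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree)
    labels = [v.label for v in root.postorder() if v.is_leaf()]
    dup = {x for x in labels if labels.count(x) > 1}
    if dup:
        raise ValidationError(f"duplicate leaf labels: {sorted(dup)}")
    if len(labels) < 2:
        raise ValidationError("tree must have at least 2 leaves")
    return root


def _suppress_root_bifurcation(root: Node) -> Node:
    """Unrooted normalisation: merge the two edges of a degree-2 root."""
    if len(root.children) != 2:
        return root
    a, b = root.children
    joined = a.length + b.length
    if a.is_leaf() and b.is_leaf():
        # two-taxon tree: hang one leaf under the other
        a.length = 0.0
        b.length = joined
        a.children = [b]
        return a
    if a.is_leaf():
        a, b = b, a
    # a internal: make it the embedding root, absorb b as an extra child
    b.length = joined
    a.children.append(b)
    a.length = 0.0
    return a


# ---------------------------------------------------------------------------
# containers


class SuperTree:
    """Rooted strictly binary tree with stable integer edge ids.

    Edge ids are assigned canonically (postorder after sorting children by
    smallest descendant label), so the same topology always yields the same
    ids regardless of the Newick rotation it was read from.
    """

    def __init__(self, root: Node):
        self.root = root
        root.sort_canonical()
        self._edges: list[Node] = []
        for v in root.postorder():
            if v is root:
                continue
            v.edge_id = len(self._edges)
            self._edges.append(v)
        self._validate()
        self.taxa = root.leaf_labels()

    def _validate(self) -> None:
        for v in self.root.postorder():
            if v.children and len(v.children) != 2:
                raise ValidationError(
                    "supertree must be strictly binary (every internal node, "
                    f"including the root, has 2 children; found {len(v.children)})"
                )

    # -- basic accessors ----------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.taxa)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edge_lengths(self):
        import numpy as np

        return np.array([e.length for e in self._edges], dtype=float)

    def with_edge_lengths(self, t: Sequence[float]) -> "SuperTree":
        if len(t) != self.n_edges:
            raise ValueError(f"expected {self.n_edges} lengths, got {len(t)}")
        root = self.root.copy()
        out = SuperTree(root)
        for e, x in zip(out._edges, t):
            e.length = float(x)
        return out

    def edge_node(self, edge_id: int) -> Node:
        return self._edges[edge_id]

    def leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def rec(v: Node, d: float) -> None:
            if v.is_leaf():
                depths[v.label] = d
            for c in v.children:
                rec(c, d + c.length)

        rec(self.root, 0.0)
        return depths

    def clades(self) -> set[frozenset[str]]:
        return {
            v.leaf_labels() for v in self.root.postorder() if v.children
        } | {frozenset([v.label]) for v in self.root.postorder() if v.is_leaf()}

    def newick(self) -> str:
        return self.root.newick()

    # -- restriction ---------------------------------------------------------
    def restrict(self, keep: Iterable[str]):
        """Induced rooted subtree on ``keep``, rooted at their MRCA.

        Returns ``(subtree, composition)`` where ``composition`` maps each
        edge id of the restricted tree to the frozenset of original edge ids
        whose lengths were summed into it.  Original edges above the MRCA of
        ``keep`` appear in no composition.
        """
        keep = frozenset(keep)
        _check_keep(keep, self.taxa, minimum=2)
        ids_of: dict[int, frozenset[int]] = {}

        def induce(v: Node) -> tuple[Node, float, frozenset[int]] | None:
            own = frozenset() if v.edge_id is None else frozenset([v.edge_id])
            if v.is_leaf():
                if v.label not in keep:
                    return None
                return Node(v.label), v.length, own
            got = [r for r in (induce(c) for c in v.children) if r is not None]
            if not got:
                return None
            if len(got) == 1:
                node, ln, ids = got[0]
                return node, ln + v.length, ids | own
            new = Node(v.label)
            for node, ln, ids in got:
                node.length = ln
                ids_of[id(node)] = ids
                new.children.append(node)
            return new, v.length, own

        res = induce(self.root)
        assert res is not None
        new_root = res[0]
        new_root.length = 0.0
        sub = SuperTree(new_root)
        composition = {e.edge_id: ids_of[id(e)] for e in sub._edges}
        return sub, composition


class GeneTree:
    """Unrooted binary tree with branch lengths, stored as a rooted embedding.

    The embedding root is an internal node of degree 3 (or a leaf for trees
    of fewer than 4 taxa); its placement carries no information.
    """

    def __init__(self, root: Node, tree_id: int = -1):
        self.root = _suppress_root_bifurcation(root)
        self.root.sort_canonical()
        self.id = tree_id
        self.taxa = self.root.leaf_labels() | (
            {self.root.label} if self.root.label is not None else set()
        )
        self._validate()

    def _validate(self) -> None:
        # degree = #children + (1 if not embedding root)
        for v in self.root.postorder():
            deg = len(v.children) + (0 if v is self.root else 1)
            if v.children and v.label is None and deg not in (3,):
                if not (v is self.root and deg in (1, 2, 3)):
                    raise ValidationError(
                        f"gene tree must be unrooted binary; found degree {deg}"
                    )
            if v.length < 0:
                raise ValidationError("negative branch length")

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_edges(self) -> int:
        return sum(1 for v in self.root.postorder() if v is not self.root)

    # -- unrooted edge identities -------------------------------------------
    def bipartitions(self) -> dict[frozenset[str], float]:
        """Map each edge's canonical bipartition side to its length.

        The canonical side of an edge is the half not containing the
        lexicographically smallest taxon.
        """
        ref = min(self.taxa)
        out: dict[frozenset[str], float] = {}
        for v in self.root.postorder():
            if v is self.root:
                continue
            below = v.leaf_labels()
            side = below if ref not in below else self.taxa - below
            out[frozenset(side)] = v.length
        return out

    def topology_key(self) -> frozenset[frozenset[str]]:
        return frozenset(self.bipartitions())

    def pairwise_distances(self) -> dict[frozenset[str], float]:
        """Leaf-to-leaf path lengths (used by conservation checks)."""
        dists: dict[frozenset[str], float] = {}

        def rec(v: Node) -> dict[str, float]:
            if v.is_leaf():
                below = {v.label: 0.0}
            else:
                below = {}
                for c in v.children:
                    sub = rec(c)
                    for a, da in sub.items():
                        for b, db in below.items():
                            dists[frozenset((a, b))] = da + db
                    below.update(sub)
            if v.label is not None and v.children:  # embedding root is a leaf
                for a, da in below.items():
                    if a != v.label:
                        dists[frozenset((a, v.label))] = da
                below[v.label] = 0.0
            return {a: d + v.length for a, d in below.items()}

        rec(self.root)
        return dists

    def restrict(self, keep: Iterable[str]) -> "GeneTree":
        keep = frozenset(keep)
        _check_keep(keep, self.taxa, minimum=2)

        def induce(v: Node) -> tuple[Node, float] | None:
            kids = []
            if v.label is not None and v.label in keep:
                kids.append((Node(v.label), 0.0))
            for c in v.children:
                r = induce(c)
                if r is not None:
                    kids.append(r)
            if not kids:
                return None
            if len(kids) == 1 and not (v.label is not None and v.label in keep):
                node, ln = kids[0]
                return node, ln + v.length
            if len(kids) == 1:
                return kids[0][0], kids[0][1] + v.length
            new = Node()
            for node, ln in kids:
                node.length = ln
                new.children.append(node)
            return new, v.length

        res = induce(self.root)
        assert res is not None
        root = res[0]
        root.length = 0.0
        return GeneTree(root, self.id)

    def adjacency(self):
        """Undirected view: (nodes, edges) with edges as (u, v, length, bip).

        Node objects are reused; ``bip`` is the canonical bipartition of the
        edge (see :meth:`bipartitions`).
        """
        ref = min(self.taxa)
        edges = []
        for v in self.root.postorder():
            if v is self.root:
                continue
            below = v.leaf_labels()
            side = below if ref not in below else self.taxa - below
            edges.append((v, frozenset(side), v.length))
        return edges

    def newick(self) -> str:
        root = self.root
        if root.label is not None and root.children:
            # serialise the leaf-rooted small-tree embedding symmetrically
            wrap = Node()
            leaf = Node(root.label, 0.0)
            wrap.children = [leaf] + [c.copy() for c in root.children]
            return wrap.newick()
        return root.newick()


def _check_keep(keep: frozenset, taxa: frozenset, minimum: int) -> None:
    extra = keep - taxa
    if extra:
        raise ValidationError(f"labels not in tree: {sorted(extra)}")
    if len(keep) < minimum:
        raise ValidationError(f"need at least {minimum} leaves, got {len(keep)}")


# ---------------------------------------------------------------------------
# public I/O


def read_newick_tree(text: str, rooted: bool, tree_id: int = -1):
    """Parse one Newick string into a :class:`SuperTree` or :class:`GeneTree`.

    Unrooted reading suppresses a degree-2 root, summing the two incident
    branch lengths into one edge.  Bracketed comments/annotations are
    discarded by the parser; support values on internal nodes are ignored.
    """
    root = _parse_newick(text)
    if rooted:
        return SuperTree(root)
    return GeneTree(root, tree_id)


def read_forest(path, supertree: SuperTree | None = None) -> list[GeneTree]:
    """Read a forest: one unrooted Newick per line, ids by line order.

    If ``supertree`` is given, every leaf label is validated against its
    taxon set and unknown labels raise :class:`ValidationError`.
    """
    trees: list[GeneTree] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                gt = read_newick_tree(line, rooted=False, tree_id=len(trees))
            except (NewickError, ValidationError) as exc:
                raise type(exc)(f"line {lineno}: {exc}") from exc
            if supertree is not None:
                unknown = gt.taxa - supertree.taxa
                if unknown:
                    raise ValidationError(
                        f"line {lineno}: leaf label(s) not in supertree: "
                        f"{sorted(unknown)}"
                    )
            trees.append(gt)
    if not trees:
        raise ValidationError(f"no trees found in {path}")
    return trees


def write_forest(path, forest: Iterable[GeneTree]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gt in forest:
            fh.write(gt.newick() + "\n")


def read_taxon_set(path) -> frozenset[str]:
    with open(path, "r", encoding="utf-8") as fh:
        labels = [ln.strip() for ln in fh if ln.strip()]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate labels in taxon set file")
    return frozenset(labels)


def restrict_tree(tree, keep: Iterable[str]):
    """Induced subtree on ``keep`` with degree-2 suppression (lengths summed).

    Dispatches on tree kind; for a supertree only the tree (not the edge
    composition record) is returned.
    """
    if isinstance(tree, SuperTree):
        return tree.restrict(keep)[0]
    return tree.restrict(keep)
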