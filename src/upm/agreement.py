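"""Maximum agreement subtrees and gene-tree → supertree edge mapping.

The pacemaker fit requires every gene-tree edge to map to a path of
supertree edges.  That is only possible on a leaf set where the two trees
agree topologically, so each gene tree is first reduced to its maximum
agreement subtree (MAST) with the supertree.

The rooted MAST of two binary trees is computed by the classic dynamic
program over node pairs: the agreement value of a pair is the best of
matching the two children pairs (both ways) or descending on either side.
A gene tree is unrooted, so its MAST with the rooted supertree is taken as
the maximum over all edge rootings of the gene tree.  Ties — between
co-optimal leaf sets and between co-optimal rootings — are broken toward
the lexicographically smallest sorted leaf-label tuple, making results
deterministic (co-optimal MASTs can differ slightly in downstream E²).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .forest_io import GeneTree, Node, SuperTree, ValidationError

__all__ = [
    "MastResult",
    "MappedRow",
    "MappedForest",
    "rooted_mast",
    "mast_vs_supertree",
    "reduce_and_map",
    "build_mapped_forest",
    "choose_supertree",
]


@dataclass(frozen=True)
class MastResult:
    gene_id: int
    leaves: frozenset[str]
    size: int
    leaves_orig: int  # leaf count of the gene tree before reduction

    @property
    def mg(self) -> float:
        """Fraction of the original gene-tree leaves retained in the MAST."""
        return self.size / self.leaves_orig


@dataclass(frozen=True)
class MappedRow:
    gene_id: int
    edge_id: int
    length: float
    st_path: frozenset[int]


@dataclass
class MappedForest:
    """Fit-ready design: every reduced gene-tree edge with its supertree path."""

    rows: list[MappedRow]
    n_st_edges: int
    mast_results: dict[int, MastResult] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.rows)

    def gene_ids(self) -> list[int]:
        return sorted({r.gene_id for r in self.rows})

    def covered_edges(self) -> frozenset[int]:
        out: set[int] = set()
        for r in self.rows:
            out |= r.st_path
        return frozenset(out)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\tedge_id\tlength\tst_edges\n")
            for r in self.rows:
                ids = ",".join(str(i) for i in sorted(r.st_path))
                fh.write(f"{r.gene_id}\t{r.edge_id}\t{r.length:.12g}\t{ids}\n")

    @classmethod
    def from_tsv(cls, path, n_st_edges: int) -> "MappedForest":
        rows = []
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("gene_id"):
                raise ValidationError("bad mapped-forest TSV header")
            for line in fh:
                g, e, ln, ids = line.rstrip("\n").split("\t")
                rows.append(
                    MappedRow(
                        int(g),
                        int(e),
                        float(ln),
                        frozenset(int(x) for x in ids.split(",")),
                    )
                )
        return cls(rows, n_st_edges)

    def summary(self) -> dict:
        genes = self.gene_ids()
        return {
            "n_trees": len(genes),
            "n_leaves": sum(self.mast_results[g].size for g in genes)
            if self.mast_results
            else None,
            "n_edges": self.n,
        }


# ---------------------------------------------------------------------------
# flattened rooted trees for the DP


class _Flat:
    __slots__ = ("labels", "children", "post", "root")

    def __init__(self):
        self.labels: list[str | None] = []
        self.children: list[tuple[int, ...]] = []
        self.post: list[int] = []
        self.root: int = -1

    @classmethod
    def from_node(cls, root: Node) -> "_Flat":
        f = cls()

        def rec(v: Node) -> int:
            kids = tuple(rec(c) for c in v.children)
            idx = len(f.labels)
            f.labels.append(v.label if not v.children else None)
            f.children.append(kids)
            f.post.append(idx)
            return idx

        f.root = rec(root)
        for kids in f.children:
            if len(kids) > 2:
                raise ValidationError("MAST requires binary trees")
        return f


def _gene_rootings(gt: GeneTree):
    """Yield a _Flat rooted tree for every edge rooting of the gene tree."""
    # undirected adjacency over the embedding nodes
    nodes: list[Node] = list(gt.root.postorder())
    nbr: dict[int, list[Node]] = {id(v): [] for v in nodes}
    edges: list[tuple[Node, Node]] = []
    for v in nodes:
        for c in v.children:
            nbr[id(v)].append(c)
            nbr[id(c)].append(v)
            edges.append((v, c))

    def orient(f: _Flat, v: Node, parent: Node | None) -> int:
        kids = tuple(
            orient(f, w, v) for w in nbr[id(v)] if parent is None or w is not parent
        )
        idx = len(f.labels)
        f.labels.append(v.label if not kids else None)
        f.children.append(kids)
        f.post.append(idx)
        return idx

    for u, v in edges:
        f = _Flat()
        a = orient(f, u, v)
        b = orient(f, v, u)
        idx = len(f.labels)
        f.labels.append(None)
        f.children.append((a, b))
        f.post.append(idx)
        f.root = idx
        yield f


def _mast_size(A: _Flat, B: _Flat) -> int:
    nB = len(B.labels)
    M = [[0] * nB for _ in range(len(A.labels))]
    for ia in A.post:
        ca, la = A.children[ia], A.labels[ia]
        Mi = M[ia]
        for ib in B.post:
            cb = B.children[ib]
            if not ca and not cb:
                Mi[ib] = 1 if la == B.labels[ib] else 0
                continue
            best = 0
            for c in ca:
                x = M[c][ib]
                if x > best:
                    best = x
            for c in cb:
                x = Mi[c]
                if x > best:
                    best = x
            if len(ca) == 2 and len(cb) == 2:
                a1, a2 = ca
                b1, b2 = cb
                x = M[a1][b1] + M[a2][b2]
                if x > best:
                    best = x
                x = M[a1][b2] + M[a2][b1]
                if x > best:
                    best = x
            Mi[ib] = best
    return M[A.root][B.root]


def _better(x: tuple[str, ...], y: tuple[str, ...]) -> tuple[str, ...]:
    """Prefer larger leaf sets; among equals, the lexicographically smaller."""
    if len(x) != len(y):
        return x if len(x) > len(y) else y
    return min(x, y)


def _mast_set(A: _Flat, B: _Flat) -> tuple[str, ...]:
    nB = len(B.labels)
    empty: tuple[str, ...] = ()
    M: list[list[tuple[str, ...]]] = [[empty] * nB for _ in range(len(A.labels))]
    for ia in A.post:
        ca, la = A.children[ia], A.labels[ia]
        Mi = M[ia]
        for ib in B.post:
            cb = B.children[ib]
            if not ca and not cb:
                Mi[ib] = (la,) if la == B.labels[ib] else empty
                continue
            best = empty
            for c in ca:
                best = _better(best, M[c][ib])
            for c in cb:
                best = _better(best, Mi[c])
            if len(ca) == 2 and len(cb) == 2:
                a1, a2 = ca
                b1, b2 = cb
                best = _better(
                    best, tuple(sorted(M[a1][b1] + M[a2][b2]))
                )
                best = _better(
                    best, tuple(sorted(M[a1][b2] + M[a2][b1]))
                )
            Mi[ib] = best
    return M[A.root][B.root]


def _as_root_node(tree) -> Node:
    if isinstance(tree, SuperTree):
        return tree.root
    if isinstance(tree, Node):
        return tree
    raise TypeError(f"expected a rooted tree, got {type(tree).__name__}")


def rooted_mast(a, b) -> frozenset[str]:
    """Maximum agreement leaf set of two rooted binary trees.

    Among co-optimal sets the one with the lexicographically smallest
    sorted label tuple is returned.
    """
    A = _Flat.from_node(_as_root_node(a))
    B = _Flat.from_node(_as_root_node(b))
    return frozenset(_mast_set(A, B))


def _unrooted_key_of_rooted(root: Node, taxa: frozenset[str]):
    """Canonical unrooted bipartition set of a rooted tree (for fast paths)."""
    ref = min(taxa)
    out = set()
    for v in root.postorder():
        if v is root:
            continue
        below = v.leaf_labels()
        side = below if ref not in below else taxa - below
        out.add(frozenset(side))
    return frozenset(out)


def mast_vs_supertree(gt: GeneTree, st: SuperTree) -> MastResult:
    """MAST of an unrooted gene tree with the rooted supertree.

    The supertree is first restricted to the gene's leaf set; the result is
    the maximum over all edge rootings of the gene tree of the rooted MAST
    with that restriction (the rooted DP's descend moves make node rootings
    redundant).
    """
    if not gt.taxa <= st.taxa:
        raise ValidationError(
            f"gene tree leaves not in supertree: {sorted(gt.taxa - st.taxa)}"
        )
    st_r, _ = st.restrict(gt.taxa)
    # fast path: topologically concordant gene tree
    if _unrooted_key_of_rooted(st_r.root, gt.taxa) == gt.topology_key():
        return MastResult(gt.id, gt.taxa, len(gt.taxa), gt.n_leaves)

    A = _Flat.from_node(st_r.root)
    rootings = list(_gene_rootings(gt))
    sizes = [_mast_size(A, B) for B in rootings]
    best = max(sizes)
    best_tuple: tuple[str, ...] | None = None
    for B, s in zip(rootings, sizes):
        if s == best:
            cand = _mast_set(A, B)
            best_tuple = cand if best_tuple is None else _better(best_tuple, cand)
    assert best_tuple is not None and len(best_tuple) == best
    return MastResult(gt.id, frozenset(best_tuple), best, gt.n_leaves)


def reduce_and_map(
    gt: GeneTree, mast: MastResult, st: SuperTree
) -> list[MappedRow]:
    """Reduce a gene tree to its MAST leaves and map edges to supertree paths.

    The reduced gene tree and the supertree restricted to the MAST leaves
    share an unrooted topology, so edges are matched by leaf bipartition.
    The two child edges of the restricted supertree's root form a single
    unrooted edge whose path is the union of both root-child compositions.
    """
    if mast.size < 4:
        raise ValidationError(f"MAST too small to map (size {mast.size} < 4)")
    rgt = gt.restrict(mast.leaves)
    st_r, comp = st.restrict(mast.leaves)

    ref = min(mast.leaves)
    path_by_bip: dict[frozenset[str], set[int]] = {}
    for v in st_r.root.postorder():
        if v is st_r.root:
            continue
        below = v.leaf_labels()
        side = below if ref not in below else mast.leaves - below
        path_by_bip.setdefault(frozenset(side), set()).update(comp[v.edge_id])

    rows: list[MappedRow] = []
    bips = rgt.bipartitions()
    if set(bips) != set(path_by_bip):
        raise ValidationError(
            "internal consistency error: reduced gene tree and restricted "
            "supertree disagree topologically (MAST is invalid)"
        )
    ordered = sorted(bips, key=lambda b: (len(b), tuple(sorted(b))))
    for i, bip in enumerate(ordered):
        rows.append(
            MappedRow(gt.id, i, bips[bip], frozenset(path_by_bip[bip]))
        )
    return rows


def build_mapped_forest(
    forest: list[GeneTree], st: SuperTree, min_mast: int = 10
) -> MappedForest:
    """Reduce and map every gene tree, discarding MASTs below ``min_mast``."""
    if min_mast < 4:
        raise ValueError("min_mast must be at least 4")
    rows: list[MappedRow] = []
    masts: dict[int, MastResult] = {}
    for gt in forest:
        mast = mast_vs_supertree(gt, st)
        if mast.size < min_mast:
            continue
        rows.extend(reduce_and_map(gt, mast, st))
        masts[gt.id] = mast
    if not rows:
        raise ValidationError(
            f"no gene tree passed the MAST size threshold {min_mast}"
        )
    return MappedForest(rows, st.n_edges, masts)


def choose_supertree(
    candidates: list[SuperTree], forest: list[GeneTree], min_mast: int = 10
) -> int:
    """Index of the candidate maximizing total MAST leaves (first on ties)."""
    if not candidates:
        raise ValueError("no candidate supertrees")
    totals = []
    for st in candidates:
        tot = 0
        for gt in forest:
            mast = mast_vs_supertree(gt, st)
            if mast.size >= min_mast:
                tot += mast.size
        totals.append(tot)
    return max(range(len(candidates)), key=lambda i: (totals[i], -i))


def write_summary(mf: MappedForest, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(mf.summary(), fh, indent=2)
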