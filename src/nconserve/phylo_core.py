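"""Rooted-tree container and the distance/clade primitives used by every statistic.

Trees are stored as read: no re-rooting is performed, because clade-depth
statistics depend on root placement and that choice belongs to the caller.
Newick parsing and serialisation are delegated to :mod:`dendropy`; on top of
the dendropy tree we maintain a flat array index (:class:`TreeIndex`) so the
permutation-heavy statistics can run vectorised.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import skbio

__all__ = [
    "PhyloTree",
    "TreeIndex",
    "read_newick",
    "write_newick",
    "mean_node_depth",
    "patristic_distance_matrix",
    "nearest_neighbor_distance",
    "resolve_polytomies",
    "read_distance_matrix",
    "write_distance_matrix",
]


class NewickError(ValueError):
    """Malformed newick input (message carries the parser's position info)."""


class TreeIndex:
    """Flat, array-backed view of a rooted tree in preorder.

    Node ``i`` is the ``i``-th node of a preorder traversal (root = 0).
    All per-node quantities used by the statistics — parent pointers,
    branch lengths, descendant-tip counts, mean node-to-tip depth — are
    precomputed once so trait permutations only touch numpy arrays.
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.preorder_node_iter())
        self.n_nodes = n = len(nodes)
        self._nodes = nodes
        pos = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(n, -1, dtype=np.int64)
        self.edge_len = np.zeros(n)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, nd in enumerate(nodes):
            if i > 0:
                p = pos[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.edge_len[i] = nd.edge.length if nd.edge.length is not None else 0.0
        self.is_tip = np.array([not nd.child_nodes() for nd in nodes])
        self.tip_ids = np.flatnonzero(self.is_tip)
        self.tip_labels = [
            nodes[i].taxon.label if nodes[i].taxon is not None else (nodes[i].label or "")
            for i in self.tip_ids
        ]
        self.tip_pos = {lab: k for k, lab in enumerate(self.tip_labels)}
        self.postorder = np.array([pos[id(nd)] for nd in tree.postorder_node_iter()])

        # subtree tip counts and summed node-to-tip distances (postorder sweep)
        self.n_desc_tips = np.zeros(n, dtype=np.int64)
        sum_tip_dist = np.zeros(n)
        for i in self.postorder:
            if self.is_tip[i]:
                self.n_desc_tips[i] = 1
            else:
                for c in self.children[i]:
                    self.n_desc_tips[i] += self.n_desc_tips[c]
                    sum_tip_dist[i] += sum_tip_dist[c] + self.n_desc_tips[c] * self.edge_len[c]
        with np.errstate(invalid="ignore"):
            self.mean_depth = sum_tip_dist / self.n_desc_tips

        self.depth_from_root = np.zeros(n)
        for i in range(1, n):
            self.depth_from_root[i] = self.depth_from_root[self.parent[i]] + self.edge_len[i]

        self._patristic: np.ndarray | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def patristic(self) -> np.ndarray:
        """Dense tip × tip patristic matrix, rows/cols in ``tip_labels`` order."""
        if self._patristic is None:
            nt = self.n_tips
            D = np.zeros((nt, nt))
            # per node: (tip rows, distances tip->node); merged bottom-up
            carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            tip_row = np.full(self.n_nodes, -1, dtype=np.int64)
            tip_row[self.tip_ids] = np.arange(nt)
            for i in self.postorder:
                if self.is_tip[i]:
                    carry[i] = (np.array([tip_row[i]]), np.zeros(1))
                    continue
                parts = []
                for c in self.children[i]:
                    rows, dist = carry.pop(c)
                    parts.append((rows, dist + self.edge_len[c]))
                for a in range(len(parts)):
                    ra, da = parts[a]
                    for b in range(a + 1, len(parts)):
                        rb, db = parts[b]
                        block = da[:, None] + db[None, :]
                        D[np.ix_(ra, rb)] = block
                        D[np.ix_(rb, ra)] = block.T
                carry[i] = (
                    np.concatenate([p[0] for p in parts]),
                    np.concatenate([p[1] for p in parts]),
                )
            self._patristic = D
        return self._patristic


class PhyloTree:
    """A rooted phylogeny with branch lengths in substitutions/site.

    Invariants enforced at construction: a single root, unique non-empty
    tip labels, finite non-negative branch lengths. Missing branch lengths
    are set to 0 with a warning. Polytomies are allowed; consumers that
    need a bifurcating tree resolve them via :func:`resolve_polytomies`.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._index: TreeIndex | None = None

    def _validate(self) -> None:
        labels: list[str] = []
        for leaf in self._tree.leaf_node_iter():
            lab = leaf.taxon.label if leaf.taxon is not None else (leaf.label or "")
            if not lab:
                raise ValueError("empty tip label")
            labels.append(lab)
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        n_missing = 0
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            bl = nd.edge.length
            if bl is None:
                nd.edge.length = 0.0
                n_missing += 1
            elif not np.isfinite(bl):
                raise ValueError("non-finite branch length")
            elif bl < 0:
                raise ValueError(f"negative branch length {bl}")
        if n_missing:
            warnings.warn(f"{n_missing} branch length(s) missing; set to 0", stacklevel=3)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def index(self) -> TreeIndex:
        if self._index is None:
            self._index = TreeIndex(self._tree)
        return self._index

    @property
    def tip_labels(self) -> list[str]:
        return list(self.index.tip_labels)

    @property
    def n_tips(self) -> int:
        return self.index.n_tips

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Restrict to the given tips; branch lengths through removed
        degree-2 nodes are summed."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)[:5]}")
        t = self._tree.clone(depth=1)
        t.retain_taxa_with_labels(sorted(keep))
        return PhyloTree(t)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"


def read_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Internal-node labels (often bootstrap supports) are tolerated and
    preserved. Raises :class:`NewickError` on malformed input and
    ``ValueError`` on duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy error messages carry position info
        raise NewickError(f"newick parse error: {exc}") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    return tree.dendropy_tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def _node_index(tree: PhyloTree, node) -> int:
    ix = tree.index
    if isinstance(node, (int, np.integer)):
        if not 0 <= int(node) < ix.n_nodes:
            raise KeyError(f"unknown node id {node}")
        return int(node)
    if isinstance(node, str):
        if node in ix.tip_pos:
            return int(ix.tip_ids[ix.tip_pos[node]])
        raise KeyError(f"unknown node label {node!r}")
    raise TypeError("node must be a preorder index or a tip label")


def mean_node_depth(tree: PhyloTree, node) -> float:
    """Genetic depth of a node: mean path length to its descendant tips.

    Tips have depth 0. ``node`` is a preorder index or a tip label.
    """
    return float(tree.index.mean_depth[_node_index(tree, node)])


def patristic_distance_matrix(tree: PhyloTree) -> skbio.DistanceMatrix:
    """Pairwise sum of branch lengths between all tips."""
    if tree.n_tips < 2:
        raise ValueError("patristic distances need at least 2 tips")
    return skbio.DistanceMatrix(tree.index.patristic(), ids=tree.index.tip_labels)


def nearest_neighbor_distance(tree: PhyloTree, tip: str) -> float:
    """Minimum patristic distance from ``tip`` to any other tip."""
    ix = tree.index
    if tip not in ix.tip_pos:
        raise KeyError(f"unknown tip {tip!r}")
    if ix.n_tips < 2:
        raise ValueError("nearest neighbor needs at least 2 tips")
    row = ix.patristic()[ix.tip_pos[tip]].copy()
    row[ix.tip_pos[tip]] = np.inf
    return float(row.min())


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Return a bifurcating copy; multifurcations are split deterministically
    in child order, inserting zero-length branches (ties therefore persist
    in downstream distances, which is intended)."""
    t = tree.dendropy_tree.clone(depth=1)
    for nd in list(t.preorder_node_iter()):
        while len(nd.child_nodes()) > 2:
            kids = nd.child_nodes()
            a, b = kids[0], kids[1]
            nd.remove_child(a)
            nd.remove_child(b)
            merged = dendropy.Node()
            merged.edge.length = 0.0
            merged.add_child(a)
            merged.add_child(b)
            nd.insert_child(0, merged)
    return PhyloTree(t)


def write_distance_matrix(dm: skbio.DistanceMatrix, path) -> None:
    """Labelled square TSV (header row and column of tip labels)."""
    dm.write(str(path), format="lsmat")


def read_distance_matrix(path) -> skbio.DistanceMatrix:
    return skbio.DistanceMatrix.read(str(path), format="lsmat")
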