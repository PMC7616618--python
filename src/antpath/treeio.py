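"""Rooted time-calibrated trees: parsing, pruning, rescaling and covariance.

Trees are stored as :class:`dendropy.Tree` objects wrapped in
:class:`Phylogeny`, which adds an array-based index (:class:`TreeIndex`)
consumed by the likelihood kernels, plus the phylogenetic covariance
construction used by the GLS and mixed-model machinery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeSample",
    "TreeIndex",
    "PhyloCovariance",
    "NewickError",
    "read_trees",
    "normalize_label",
    "match_species_to_tips",
]


class NewickError(ValueError):
    """Raised for malformed or invalid tree input."""


def normalize_label(label: str) -> str:
    """Canonical form used when matching species names to tree tips.

    Case-insensitive; spaces and underscores interchangeable.
    """
    return re.sub(r"[\s_]+", "_", label.strip()).lower()


def match_species_to_tips(names: Iterable[str], tip_labels: Sequence[str]):
    """Map species names onto tree tip labels.

    Returns ``(mapping, unmatched)`` where ``mapping`` maps each input name to
    the tip label it resolved to and ``unmatched`` lists names absent from the
    tree.
    """
    lookup = {normalize_label(t): t for t in tip_labels}
    mapping, unmatched = {}, []
    for name in names:
        tip = lookup.get(normalize_label(name))
        if tip is None:
            unmatched.append(name)
        else:
            mapping[name] = tip
    return mapping, unmatched


@dataclass
class TreeIndex:
    """Array view of a rooted tree.

    Node indices: tips are ``0 .. n_tips-1`` (postorder order of first
    appearance), internal nodes follow in postorder, so the root is the last
    index.  ``edge_length[v]`` is the branch above node ``v`` (0 for the
    root).  ``postorder`` lists internal nodes children-first.
    """

    n_tips: int
    n_nodes: int
    parent: np.ndarray
    edge_length: np.ndarray
    postorder: np.ndarray
    children_flat: np.ndarray
    children_ptr: np.ndarray
    tip_labels: list[str]
    root: int

    @property
    def n_internal(self) -> int:
        return self.n_nodes - self.n_tips

    def children(self, v: int) -> np.ndarray:
        return self.children_flat[self.children_ptr[v]:self.children_ptr[v + 1]]

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths.

        A non-zero root (stem) edge — e.g. left behind by pruning a basal
        taxon — counts toward every depth, so pruning preserves depths.
        """
        depth = np.zeros(self.n_nodes)
        depth[self.root] = self.edge_length[self.root]
        for v in self.preorder_nodes():
            if self.parent[v] >= 0:
                depth[v] = depth[self.parent[v]] + self.edge_length[v]
        return depth

    def preorder_nodes(self) -> np.ndarray:
        stack = [self.root]
        order = []
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children(v)[::-1])
        return np.array(order, dtype=np.int64)

    def subtree_membership(self) -> np.ndarray:
        """Boolean matrix M[v, u] = node u lies in the subtree rooted at v."""
        M = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for v in range(self.n_tips):
            M[v, v] = True
        for v in self.postorder:
            M[v, v] = True
            for c in self.children(v):
                M[v] |= M[c]
        return M


def _build_index(tree: dendropy.Tree) -> TreeIndex:
    nodes = list(tree.postorder_node_iter())
    tips = [n for n in nodes if n.is_leaf()]
    internals = [n for n in nodes if not n.is_leaf()]
    idx: dict[int, int] = {}
    for i, n in enumerate(tips):
        idx[id(n)] = i
    for j, n in enumerate(internals):
        idx[id(n)] = len(tips) + j
    n_nodes = len(nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    edge_length = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for n in nodes:
        v = idx[id(n)]
        if n.edge.length is not None:
            edge_length[v] = float(n.edge.length)
        if n.parent_node is not None:
            p = idx[id(n.parent_node)]
            parent[v] = p
            children[p].append(v)
    ptr = np.zeros(n_nodes + 1, dtype=np.int64)
    for v in range(n_nodes):
        ptr[v + 1] = ptr[v] + len(children[v])
    flat = np.array([c for cs in children for c in cs], dtype=np.int64)
    labels = [t.taxon.label if t.taxon is not None else "" for t in tips]
    return TreeIndex(
        n_tips=len(tips),
        n_nodes=n_nodes,
        parent=parent,
        edge_length=edge_length,
        postorder=np.array([idx[id(n)] for n in internals], dtype=np.int64),
        children_flat=flat,
        children_ptr=ptr,
        tip_labels=labels,
        root=idx[id(tree.seed_node)],
    )


@dataclass
class PhyloCovariance:
    """Shared-path-length covariance with Pagel's lambda scaling.

    ``matrix[i, j]`` is the root-to-MRCA path length of taxa ``i`` and ``j``
    with off-diagonal entries multiplied by ``lam``.  ``taxa`` may include
    internal-node identifiers when built with ``include_internal=True``.
    """

    taxa: list[str]
    matrix: np.ndarray
    lam: float = 1.0
    include_internal: bool = False

    def scaled(self, lam: float) -> "PhyloCovariance":
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        base = self.matrix.copy()
        d = np.diag(base).copy()
        base *= lam / (self.lam if self.lam > 0 else 1.0)
        np.fill_diagonal(base, d)
        return PhyloCovariance(self.taxa, base, lam, self.include_internal)


class Phylogeny:
    """A rooted tree with branch lengths in time units."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index: TreeIndex | None = None
        labels = [t.taxon.label for t in tree.leaf_node_iter() if t.taxon is not None]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        for node in tree.preorder_node_iter():
            if node.edge.length is not None and node.edge.length < 0:
                raise NewickError(f"negative branch length {node.edge.length}")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def write_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- basic properties --------------------------------------------------
    @property
    def index(self) -> TreeIndex:
        if self._index is None:
            self._index = _build_index(self._tree)
        return self._index

    @property
    def tip_labels(self) -> list[str]:
        return list(self.index.tip_labels)

    @property
    def n_tips(self) -> int:
        return self.index.n_tips

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        d = self.index.depths()
        return float(d[: self.index.n_tips].max())

    # -- operations --------------------------------------------------------
    def prune_to_taxa(self, taxa: Iterable[str]) -> "Phylogeny":
        """Induced subtree on ``taxa``; unifurcations collapse additively."""
        taxa = list(taxa)
        mapping, unmatched = match_species_to_tips(taxa, self.tip_labels)
        if unmatched:
            raise KeyError(f"taxa not found in tree: {unmatched}")
        keep = set(mapping.values())
        if len(keep) < 2:
            raise ValueError("pruning must retain at least 2 taxa")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        # a leftover root unifurcation keeps depths intact; nothing to do
        return Phylogeny(sub)

    def scale_branches(self, factor: float) -> "Phylogeny":
        if factor <= 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Phylogeny(clone)

    def covariance(self, lam: float = 1.0, include_internal: bool = False) -> PhyloCovariance:
        """Phylogenetic covariance: shared path length from the root.

        ``C[i, j]`` sums the branch lengths ancestral to both ``i`` and
        ``j``; the diagonal holds node depths.  Off-diagonals are multiplied
        by ``lam``.  With ``include_internal`` the matrix covers tips followed
        by internal nodes (identifiers ``node<i>``).
        """
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        ix = self.index
        M = ix.subtree_membership()  # (n_nodes, n_nodes)
        if include_internal:
            sel = np.arange(ix.n_nodes)
            taxa = list(ix.tip_labels) + [f"node{v}" for v in range(ix.n_tips, ix.n_nodes)]
        else:
            sel = np.arange(ix.n_tips)
            taxa = list(ix.tip_labels)
        # C = sum_v len(v) * [v ancestral-or-self to i] * [v ancestral-or-self to j]
        A = M[:, sel].astype(float)  # A[v, i]: i in subtree of v
        C = (A * ix.edge_length[:, None]).T @ A
        C = np.asarray(C)
        d = np.diag(C).copy()
        C *= lam
        np.fill_diagonal(C, d)
        return PhyloCovariance(taxa, C, lam, include_internal)


@dataclass
class TreeSample:
    """An ordered posterior sample of trees over a shared tip universe."""

    trees: list[Phylogeny] = field(default_factory=list)

    def __post_init__(self):
        if self.trees:
            tips0 = set(map(normalize_label, self.trees[0].tip_labels))
            for i, t in enumerate(self.trees[1:], 1):
                tips = set(map(normalize_label, t.tip_labels))
                if tips != tips0:
                    raise ValueError(f"tree {i} has a different tip set than tree 0")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    def prune_to_taxa(self, taxa: Iterable[str]) -> "TreeSample":
        taxa = list(taxa)
        return TreeSample([t.prune_to_taxa(taxa) for t in self.trees])


def read_trees(path: str, schema: str = "newick") -> TreeSample:
    """Read one or more trees (multi-tree Newick or a Nexus TREES block)."""
    try:
        tl = dendropy.TreeList.get(path=path, schema=schema, rooting="force-rooted")
    except Exception as exc:
        raise NewickError(f"could not read trees from {path}: {exc}") from exc
    return TreeSample([Phylogeny(t) for t in tl])
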