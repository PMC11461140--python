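"""Phylogenies, pruning, and the phylogenetic variance-covariance matrix.

The tree is the source of the residual covariance structure used by every
downstream model: under Brownian motion, the covariance of trait values of
two extant species equals the evolutionary time they share on the tree
(root-to-MRCA path length).  Pagel's lambda rescales the shared (off-diagonal)
part of that matrix, interpolating between a star phylogeny (lambda = 0,
phylogenetic independence) and the untransformed Brownian structure
(lambda = 1).

Newick parsing is delegated to dendropy; everything downstream operates on a
compact array representation (parent pointers + branch lengths) so that the
VCV matrix can be assembled with a single incidence-matrix product.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "VCVMatrix",
    "NewickParseError",
    "MissingTaxonError",
    "normalize_label",
    "read_newick",
    "prune",
    "vcv",
    "lambda_transform",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or violates tree invariants."""


class MissingTaxonError(KeyError):
    """Raised when requested tip labels are absent from a tree."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"taxa not in tree: {', '.join(self.missing)}")


_WS_RUN = re.compile(r"[\s_]+")


def normalize_label(label: str) -> str:
    """Normalise a tip label: trim, and treat runs of spaces/underscores as one space.

    Case is preserved.  Trait tables and Newick files routinely disagree on
    the separator inside binomials ("Rana_temporaria" vs "Rana temporaria");
    normalisation makes them compare equal.
    """
    return _WS_RUN.sub(" ", label.strip())


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths, stored as parent-pointer arrays.

    Nodes are indexed 0..n_nodes-1 with the ``n_tips`` tip nodes first, in
    ``tip_labels`` order.  ``parent[i]`` is the parent index (-1 for the
    root) and ``branch_length[i]`` the length of the edge above node ``i``
    (the root may carry a nonzero stem edge, which pruning uses to preserve
    root-to-tip distances).
    """

    tip_labels: tuple[str, ...]
    parent: np.ndarray
    branch_length: np.ndarray
    root: int = field(init=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.branch_length = np.asarray(self.branch_length, dtype=float)
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise NewickParseError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = {t for t in self.tip_labels if list(self.tip_labels).count(t) > 1}
            raise NewickParseError(f"duplicate tip labels after normalisation: {sorted(dupes)}")
        if not np.all(np.isfinite(self.branch_length)):
            raise NewickParseError("non-finite branch length")
        if np.any(self.branch_length < 0):
            raise NewickParseError("negative branch length")

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def depths(self) -> np.ndarray:
        """Root-to-node distance for every node (including the root stem edge)."""
        depth = np.zeros(self.n_nodes)
        for node in self._preorder():
            p = self.parent[node]
            depth[node] = self.branch_length[node] + (depth[p] if p >= 0 else 0.0)
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.depths()[: self.n_tips]

    def _children(self) -> list[list[int]]:
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(node)
        return children

    def _preorder(self) -> list[int]:
        children = self._children()
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(children[node]))
        return order

    def to_newick(self, precision: int = 12) -> str:
        """Serialise to a Newick string (tips labelled, underscores for spaces)."""
        children = self._children()
        fmt = f"%.{precision}g"

        out: dict[int, str] = {}
        for node in reversed(self._preorder()):
            if node < self.n_tips:
                label = self.tip_labels[node].replace(" ", "_")
                out[node] = f"{label}:{fmt % self.branch_length[node]}"
            else:
                inner = ",".join(out[c] for c in children[node])
                if node == self.root and self.branch_length[node] == 0.0:
                    out[node] = f"({inner})"
                else:
                    out[node] = f"({inner}):{fmt % self.branch_length[node]}"
        return out[self.root] + ";"


def read_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree with branch lengths.

    Quoted labels and underscore-separated labels are both accepted; labels
    are normalised via :func:`normalize_label`.  Missing branch lengths are a
    hard error (no silent defaults), except on the root stem where 0 is used.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types with position info
        raise NewickParseError(f"malformed Newick input: {exc}") from exc

    tips: list[str] = []
    nodes: list = []
    index: dict[int, int] = {}

    leaves = [nd for nd in dtree.preorder_node_iter() if nd.is_leaf()]
    internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    if len(leaves) < 2:
        raise NewickParseError("tree must contain at least two tips")
    for nd in leaves:
        if nd.taxon is None or nd.taxon.label is None:
            raise NewickParseError("unlabelled tip")
        tips.append(normalize_label(nd.taxon.label))
    ordered = leaves + internals
    for i, nd in enumerate(ordered):
        index[id(nd)] = i
        nodes.append(nd)

    parent = np.full(len(ordered), -1, dtype=np.int64)
    blen = np.zeros(len(ordered))
    for nd in ordered:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickParseError(
                    f"missing branch length on edge above "
                    f"{'tip ' + tips[i] if i < len(tips) else 'an internal node'}"
                )
            blen[i] = float(nd.edge.length)
        else:
            blen[i] = float(nd.edge.length) if nd.edge.length is not None else 0.0
    return Phylogeny(tuple(tips), parent, blen)


def prune(tree: Phylogeny, keep) -> Phylogeny:
    """Prune a tree to the tip set ``keep``.

    Unary internal nodes created by the pruning are collapsed with their
    branch lengths summed; a chain above the new root is retained as a root
    stem edge, so root-to-tip distances of all retained tips are preserved
    exactly.
    """
    keep_norm = [normalize_label(k) for k in keep]
    idx = tree.tip_index()
    missing = [k for k in keep_norm if k not in idx]
    if missing:
        raise MissingTaxonError(missing)
    keep_set = {idx[k] for k in keep_norm}
    if len(keep_set) < 2:
        raise ValueError("pruning requires at least two distinct tips to keep")

    children = tree._children()
    needed = np.zeros(tree.n_nodes, dtype=bool)
    for t in keep_set:
        node = t
        while node >= 0 and not needed[node]:
            needed[node] = True
            node = tree.parent[node]

    def needed_children(node):
        return [c for c in children[node] if needed[c]]

    # walk down from the old root through any unary chain, accumulating stem length
    new_root_old = tree.root
    stem = tree.branch_length[tree.root]
    while new_root_old not in keep_set and len(needed_children(new_root_old)) == 1:
        new_root_old = needed_children(new_root_old)[0]
        stem += tree.branch_length[new_root_old]

    new_tips = sorted(keep_set, key=lambda t: tree.tip_labels[t])
    tip_labels = tuple(tree.tip_labels[t] for t in new_tips)
    n_keep = len(new_tips)
    tip_new_index = {old: i for i, old in enumerate(new_tips)}

    parent_out: list[int] = [-1] * n_keep
    blen_out: list[float] = [0.0] * n_keep

    def new_internal(par: int, length: float) -> int:
        parent_out.append(par)
        blen_out.append(length)
        return len(parent_out) - 1

    # stack of (old_node, new_parent_index, accumulated_length)
    if new_root_old in keep_set:  # cannot happen: keep_set has >=2 tips, root chain stops
        raise AssertionError("unreachable")
    root_new = new_internal(-1, stem)
    stack = [(c, root_new, tree.branch_length[c]) for c in needed_children(new_root_old)]
    while stack:
        old, par, acc = stack.pop()
        while old not in keep_set and len(needed_children(old)) == 1:
            old = needed_children(old)[0]
            acc += tree.branch_length[old]
        if old in keep_set:
            i = tip_new_index[old]
            parent_out[i] = par
            blen_out[i] = acc
        else:
            me = new_internal(par, acc)
            stack.extend(
                (c, me, tree.branch_length[c]) for c in needed_children(old)
            )
    return Phylogeny(tip_labels, np.array(parent_out), np.array(blen_out))


@dataclass
class VCVMatrix:
    """Tip-by-tip matrix of shared root-to-MRCA path lengths.

    Entry (i, j) is the depth of the most recent common ancestor of tips i
    and j; the diagonal holds root-to-tip distances.  This is the covariance
    structure of a unit-rate Brownian motion evolving along the tree.
    """

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("VCV shape does not match taxa")

    def subset(self, taxa) -> "VCVMatrix":
        order = {t: i for i, t in enumerate(self.taxa)}
        idx = np.array([order[t] for t in taxa])
        return VCVMatrix(tuple(taxa), self.values[np.ix_(idx, idx)])


def vcv(tree: Phylogeny) -> VCVMatrix:
    """Phylogenetic variance-covariance matrix of a tree.

    Computed as B diag(b) B' where B is the tips x edges incidence matrix
    (B[i, e] = 1 iff edge e lies on the root-to-tip-i path) and b the branch
    lengths — a single BLAS product even for thousands of tips.
    """
    n, m = tree.n_tips, tree.n_nodes
    B = np.zeros((n, m))
    for t in range(n):
        node = t
        while node >= 0:
            B[t, node] = 1.0
            node = tree.parent[node]
    C = (B * tree.branch_length) @ B.T
    C = 0.5 * (C + C.T)
    return VCVMatrix(tree.tip_labels, C)


def lambda_transform(V: VCVMatrix, lam: float) -> VCVMatrix:
    """Pagel's lambda transform: multiply off-diagonals by ``lam``, keep the diagonal.

    ``lam`` is deliberately unconstrained — fitted values outside [0, 1]
    occur in practice (small samples can push the optimum past either
    boundary).  A warning is emitted when the result is not positive
    definite; it is not an error, because such matrices are still reported
    by reference GLS implementations.
    """
    if not np.isfinite(lam):
        raise ValueError("lambda must be finite")
    out = lam * V.values
    np.fill_diagonal(out, np.diag(V.values))
    try:
        np.linalg.cholesky(out)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"lambda-transformed VCV is not positive definite (lambda={lam:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return VCVMatrix(V.taxa, out)
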