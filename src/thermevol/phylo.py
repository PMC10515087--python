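"""Rooted time-calibrated phylogenies: Newick I/O, pruning, phylogenetic
covariance matrices, and model-specific covariance transforms.

The tree is stored as flat parent-pointer arrays.  Branch lengths are in
time units (My for the trees this pipeline targets); the root carries a
zero-length pseudo-branch.  All covariance computations are expressed in
terms of root-to-node depths, so every operation that must preserve
species-pair covariances (pruning in particular) is specified through
depth preservation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .errors import NewickParseError, ParameterError, TreeError

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "vcv",
    "transform_covariance",
    "ou_covariance_value",
    "ULTRAMETRIC_RTOL",
]

#: Relative tip-depth spread (fraction of tree height) below which a tree
#: is treated as ultrametric.
ULTRAMETRIC_RTOL = 1e-6


class Phylogeny:
    """Rooted tree with branch lengths, parent-pointer representation.

    Parameters
    ----------
    parent : array of int
        Parent index per node; the root has parent ``-1``.
    blen : array of float
        Branch length (time) of the edge above each node; the root entry
        is ignored and stored as 0.
    labels : sequence of str or None
        Node labels; every tip (childless node) must carry a unique label.
    """

    def __init__(self, parent: Sequence[int], blen: Sequence[float],
                 labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=np.float64)
        self.labels = list(labels)
        n = self.parent.size
        if not (self.blen.size == n and len(self.labels) == n):
            raise TreeError("parent/blen/labels length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.blen[self.root] = 0.0
        self._children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                self._children[p].append(v)
        self._validate()

    # -- construction checks -------------------------------------------------

    def _validate(self) -> None:
        nonroot = np.arange(self.parent.size) != self.root
        bl = self.blen[nonroot]
        if not np.all(np.isfinite(bl)):
            raise TreeError("non-finite branch length")
        if np.any(bl < 0):
            raise TreeError("negative branch length")
        tips = self.tip_indices
        if tips.size < 1:
            raise TreeError("tree has no tips")
        labs = [self.labels[int(t)] for t in tips]
        if any(l is None or l == "" for l in labs):
            raise TreeError("unlabeled tip")
        if len(set(labs)) != len(labs):
            dup = sorted({l for l in labs if labs.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        if np.any(self.blen[tips] == 0.0) and tips.size > 1:
            warnings.warn("tree contains zero-length terminal branches; "
                          "absolute-rate computations will exclude those tips",
                          stacklevel=3)
        # cycle check via postorder size
        if self.postorder().size != self.parent.size:
            raise TreeError("parent pointers do not form a tree")

    # -- basic structure -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def children(self, v: int) -> list[int]:
        return self._children[v]

    @property
    def tip_indices(self) -> np.ndarray:
        """Indices of childless nodes, in node-id order."""
        return np.asarray([v for v in range(self.n_nodes) if not self._children[v]],
                          dtype=np.int64)

    @property
    def n_tips(self) -> int:
        return self.tip_indices.size

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in left-to-right (Newick) order."""
        return [self.labels[int(v)] for v in self._leaf_order()]

    def _leaf_order(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            kids = self._children[v]
            if not kids:
                order.append(v)
            else:
                stack.extend(reversed(kids))
        return order

    def postorder(self) -> np.ndarray:
        """Node ids in postorder (children before parents)."""
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self._children[v])
        return np.asarray(order[::-1], dtype=np.int64)

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1].copy()

    # -- depths --------------------------------------------------------------

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.blen[v]
        return d

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth."""
        return float(self.depths()[self.tip_indices].max())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        td = self.depths()[self.tip_indices]
        h = td.max()
        if h <= 0:
            return True
        return bool((td.max() - td.min()) <= rtol * h)

    def tip_depth(self, label: str) -> float:
        d = self.depths()
        for v in self.tip_indices:
            if self.labels[int(v)] == label:
                return float(d[int(v)])
        raise TreeError(f"no tip labeled {label!r}")

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.blen.copy(), list(self.labels))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, height {self.height:.4g}>"


@dataclass
class PhyloCovariance:
    """Among-species covariance structure implied by shared ancestry.

    ``matrix[i, j]`` is the root-to-MRCA depth of species ``i`` and ``j``
    (shared path length); the diagonal holds tip depths.
    """

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.species)
        if self.matrix.shape != (n, n):
            raise TreeError("covariance shape does not match species list")

    def validate(self, atol: float = 1e-10) -> None:
        C = self.matrix
        if not np.allclose(C, C.T, atol=atol):
            raise TreeError("covariance not symmetric")
        if np.any(np.diag(C) <= 0):
            raise TreeError("non-positive diagonal entry")
        w = np.linalg.eigvalsh(C)
        if w.min() < -atol * max(1.0, w.max()):
            raise TreeError("covariance not positive semi-definite")

    def reorder(self, species: Sequence[str]) -> "PhyloCovariance":
        idx = [self.species.index(s) for s in species]
        return PhyloCovariance(list(species), self.matrix[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Newick I/O (reader backed by dendropy; 9-significant-digit writer)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Every tip must be labeled and every non-root edge must carry a branch
    length.  Polytomies are preserved.  Malformed input raises
    :class:`NewickParseError` carrying the parser's position report.
    """
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports line/column in the message
        raise NewickParseError(f"Newick parse failure: {exc}") from exc

    nodes = list(dt.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    blen = np.zeros(len(nodes))
    labels: list[str | None] = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                where = nd.taxon.label if nd.taxon else f"internal node {i}"
                raise NewickParseError(
                    f"missing branch length on non-root edge at {where!r}")
            blen[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
        if nd.is_leaf() and labels[i] is None:
            raise NewickParseError(f"unlabeled tip (node {i})")
    tips = [labels[i] for i, nd in enumerate(nodes) if nd.is_leaf()]
    if len(set(tips)) != len(tips):
        dup = sorted({t for t in tips if tips.count(t) > 1})
        raise NewickParseError(f"duplicate tip labels: {dup}")
    try:
        return Phylogeny(parent, blen, labels)
    except TreeError as exc:
        raise NewickParseError(str(exc)) from exc


_NEEDS_QUOTE = set(" \t\n,():;[]'")


def _fmt_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Phylogeny, precision: int = 12) -> str:
    """Serialize with branch lengths at ``precision`` significant digits.

    The default (12) keeps absolute round-trip error below 1e-9 for
    branch lengths on the My scale of time-calibrated trees.
    """
    out = io.StringIO()
    # iterative traversal to keep deep caterpillars safe
    ENTER, EXIT = 0, 1
    stack: list[tuple[int, int, bool]] = [(tree.root, ENTER, False)]
    while stack:
        v, phase, needs_comma = stack.pop()
        if phase == ENTER:
            if needs_comma:
                out.write(",")
            kids = tree.children(v)
            if kids:
                out.write("(")
                stack.append((v, EXIT, False))
                for j, c in enumerate(reversed(kids)):
                    stack.append((c, ENTER, j < len(kids) - 1))
            else:
                out.write(_fmt_label(tree.labels[v] or ""))
                out.write(f":{tree.blen[v]:.{precision}g}")
        else:
            out.write(")")
            if tree.labels[v]:
                out.write(_fmt_label(tree.labels[v]))
            if v != tree.root:
                out.write(f":{tree.blen[v]:.{precision}g}")
    out.write(";")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Drop all tips not in ``keep``, preserving root-to-tip depths.

    Unbranched internal nodes created by the pruning are suppressed with
    their branch lengths summed.  The root is never suppressed, so every
    retained tip keeps its original depth even when the root ends up with
    a single child.
    """
    keep = set(keep)
    tip_ids = tree.tip_indices
    label_of = {int(v): tree.labels[int(v)] for v in tip_ids}
    kept_tips = [v for v in tip_ids if label_of[int(v)] in keep]
    if not kept_tips:
        unmatched = sorted(keep - set(label_of.values()))
        raise TreeError(f"no requested taxa found in tree; unmatched: {unmatched}")

    marked = np.zeros(tree.n_nodes, dtype=bool)
    for v in kept_tips:
        u = int(v)
        while u >= 0 and not marked[u]:
            marked[u] = True
            u = int(tree.parent[u])

    n_kept_children = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0 and marked[v]:
            n_kept_children[p] += 1
    is_tip = np.zeros(tree.n_nodes, dtype=bool)
    is_tip[tip_ids] = True
    remains = marked & (is_tip | (n_kept_children >= 2))
    remains[tree.root] = True

    depth = tree.depths()
    old_ids = np.flatnonzero(remains)
    new_id = {int(o): i for i, o in enumerate(old_ids)}
    parent = np.full(old_ids.size, -1, dtype=np.int64)
    blen = np.zeros(old_ids.size)
    labels: list[str | None] = []
    for o in old_ids:
        o = int(o)
        labels.append(tree.labels[o])
        if o == tree.root:
            continue
        a = int(tree.parent[o])
        while not remains[a]:
            a = int(tree.parent[a])
        parent[new_id[o]] = new_id[a]
        blen[new_id[o]] = depth[o] - depth[a]
    return Phylogeny(parent, blen, labels)


# ---------------------------------------------------------------------------
# Phylogenetic covariance and transforms
# ---------------------------------------------------------------------------

def vcv(tree: Phylogeny) -> PhyloCovariance:
    """Shared-path-length matrix: C_ij = depth of MRCA(i, j), C_ii = tip depth.

    Species are ordered as in :attr:`Phylogeny.tip_labels` (leaf order).
    """
    tips = tree._leaf_order()
    if len(tips) < 2:
        raise TreeError("vcv requires at least 2 tips")
    tix = {v: i for i, v in enumerate(tips)}
    n = len(tips)
    depth = tree.depths()
    C = np.zeros((n, n))
    tips_below: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        v = int(v)
        kids = tree.children(v)
        if not kids:
            tips_below[v] = np.asarray([tix[v]], dtype=np.int64)
            C[tix[v], tix[v]] = depth[v]
        else:
            groups = [tips_below.pop(c) for c in kids]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    C[np.ix_(groups[a], groups[b])] = depth[v]
                    C[np.ix_(groups[b], groups[a])] = depth[v]
            tips_below[v] = np.concatenate(groups)
    return PhyloCovariance([tree.labels[v] for v in tips], C)


def ou_covariance_value(m, alpha: float, tree_height: float):
    """Fixed-root (non-stationary) unit-rate OU covariance for a species
    pair whose shared root-ward path has length ``m`` on a tree of height
    ``tree_height``::

        (1 / 2a) * exp(-2a (T - m)) * (1 - exp(-2a m))

    Works elementwise on arrays; sigma^2 multiplies this structure later.
    """
    m = np.asarray(m, dtype=np.float64)
    a = float(alpha)
    return (1.0 / (2.0 * a)) * np.exp(-2.0 * a * (tree_height - m)) * (
        -np.expm1(-2.0 * a * m))


def transform_covariance(cov: PhyloCovariance, model: str, *,
                         alpha: float | None = None,
                         lam: float | None = None,
                         tree_height: float | None = None,
                         ultrametric: bool = True) -> PhyloCovariance:
    """Model-specific covariance transform.

    BM leaves C untouched; LA scales off-diagonals by lambda; WN replaces C
    by ``T * I``; OU applies the fixed-root covariance of
    :func:`ou_covariance_value`.  ``tree_height`` defaults to ``max(diag)``.
    OU demands an ultrametric source tree (pass ``ultrametric=False`` to
    signal a violation detected upstream).
    """
    C = cov.matrix
    T = float(np.max(np.diag(C))) if tree_height is None else float(tree_height)
    model = model.upper()
    if model == "BM":
        out = C.copy()
    elif model == "LA":
        if lam is None or not (0.0 <= lam <= 1.0):
            raise ParameterError(f"lambda must lie in [0, 1], got {lam}")
        out = C * lam
        np.fill_diagonal(out, np.diag(C))
    elif model == "OU":
        if alpha is None or alpha <= 0:
            raise ParameterError(f"alpha must be > 0, got {alpha}")
        if not ultrametric:
            raise ParameterError("OU transform requires an ultrametric tree")
        out = ou_covariance_value(C, alpha, T)
    elif model == "WN":
        out = T * np.eye(C.shape[0])
    else:
        raise ParameterError(f"unknown model {model!r}")
    return PhyloCovariance(list(cov.species), out)
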