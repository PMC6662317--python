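"""Functional space construction: Gower dissimilarities, principal coordinates
with the Cailliez additive correction, UPGMA dendrograms, and minimum spanning
trees.

The Gower dissimilarity averages per-trait contributions over mixed trait
types: binary traits contribute a 0/1 mismatch, the continuous trait (body
mass) contributes its absolute difference scaled by the regional-pool range.
All traits carry equal weight.  Gower output lies in [0, 1] but is in general
not Euclidean-embeddable; the Cailliez correction adds the smallest constant c
to all off-diagonal dissimilarities that makes the matrix Euclidean, so that
principal coordinates have no negative eigenvalues and the corrected geometry
is preserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import cdist, squareform

from .traits import TraitTable, ValidationError

logger = logging.getLogger(__name__)

EIG_TOL = 1e-8


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise functional distances with species labels."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.ids)}
        try:
            return np.array([pos[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"species {e.args[0]!r} absent from distance matrix") from e

    def submatrix(self, ids: Sequence[str]) -> "DissimilarityMatrix":
        idx = self.index_of(ids)
        return DissimilarityMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.index), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class TraitSpace:
    """Species coordinates from principal coordinates analysis.

    Euclidean distances between rows of ``coordinates`` (all retained axes)
    reproduce the Cailliez-corrected dissimilarities to numerical tolerance.
    """

    ids: tuple[str, ...]
    coordinates: np.ndarray  # species x axes, axes ordered by decreasing eigenvalue
    eigenvalues: np.ndarray
    cailliez_constant: float

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.ids)}
        return np.array([pos[s] for s in ids], dtype=int)

    def restrict(self, ids: Sequence[str]) -> np.ndarray:
        return self.coordinates[self.index_of(ids)]


def gower(
    traits: TraitTable,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> DissimilarityMatrix:
    """Pairwise Gower dissimilarity over the trait table.

    d_ij = (1/T) * sum_k delta_k(i, j), with delta = |x_i - x_j| for binary
    traits and |x_i - x_j| / range for continuous traits.  ``ranges`` fixes
    the continuous-trait scaling (pass the regional-pool ranges when
    computing on a subset); by default the table's own ranges are used.
    With ``schema.asymmetric_binary``, binary traits where both species score
    0 are dropped from the pair's trait count instead of counting as a match.
    """
    schema = traits.schema
    ids = tuple(traits.species)
    n = len(ids)
    if ranges is None:
        ranges = traits.continuous_ranges()

    bin_cols = list(schema.binary_traits)
    B = traits.data[bin_cols].to_numpy(dtype=float)
    # sum over binary traits of |x_i - x_j|
    mismatch = cdist(B, B, metric="cityblock") if bin_cols else np.zeros((n, n))

    cont_sum = np.zeros((n, n))
    for c in schema.continuous:
        v = traits.data[c].to_numpy(dtype=float)
        if schema.log10_mass:
            v = np.log10(v)
        lo, hi = ranges[c]
        rng = hi - lo
        if rng <= 0:
            raise ValidationError(f"continuous trait {c!r} has zero range over the pool")
        cont_sum += np.abs(v[:, None] - v[None, :]) / rng

    if schema.asymmetric_binary and bin_cols:
        # per-pair count of informative binary traits (not both-absent)
        both_zero = (1.0 - B) @ (1.0 - B.T)
        T = (len(bin_cols) - both_zero) + len(schema.continuous)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(T > 0, (mismatch + cont_sum) / T, 0.0)
    else:
        T = len(bin_cols) + len(schema.continuous)
        d = (mismatch + cont_sum) / T

    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    ties = np.argwhere(np.triu(d < 1e-15, k=1))
    if len(ties):
        logger.info("gower: %d species pair(s) are functionally identical (d = 0)", len(ties))
    return DissimilarityMatrix(ids, d)


def cailliez_constant(d: np.ndarray, tol: float | None = None) -> float:
    """Smallest additive constant c such that d_ij + c (i != j) is Euclidean.

    Computed as the largest real eigenvalue of the 2n x 2n block matrix
    [[0, 2*D1], [-I, -4*D2]] with D1, D2 the double-centered matrices of
    -d^2/2 and -d/2 respectively; clamped at 0 for already-Euclidean input.
    """
    n = d.shape[0]
    if tol is None:
        # eigenvalue noise scales with the matrix magnitude
        tol = 1e-7 * max(1.0, float(d.max()))
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * J @ (d * d) @ J
    d2 = -0.5 * J @ d @ J
    B = np.block([[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]])
    ev = np.linalg.eigvals(B)
    c = float(np.max(ev.real))
    return c if c > tol else 0.0


def pcoa_cailliez(d: DissimilarityMatrix, eig_tol: float = EIG_TOL) -> TraitSpace:
    """Principal coordinates of the Cailliez-corrected dissimilarity matrix.

    All axes with eigenvalue > ``eig_tol`` are retained, so the corrected
    geometry is represented exactly (up to numerical tolerance).
    """
    n = d.n
    if n < 3:
        raise ValidationError("principal coordinates need at least 3 species")
    c = cailliez_constant(d.values)
    dc = d.values + c
    np.fill_diagonal(dc, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (dc * dc) @ J
    w, V = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    scale = max(abs(w[0]), 1.0)
    if w[-1] < -1e-6 * scale:
        raise ValidationError(
            f"Cailliez correction failed: residual negative eigenvalue {w[-1]:.3e}"
        )
    keep = w > eig_tol
    coords = V[:, keep] * np.sqrt(w[keep])
    return TraitSpace(d.ids, coords, w[keep], c)


@dataclass(frozen=True)
class Dendrogram:
    """An average-linkage (UPGMA) dendrogram.

    ``linkage`` is a SciPy linkage matrix over ``ids`` (leaf i = ids[i]).
    UPGMA merge heights are non-decreasing and cophenetic distances are
    ultrametric.
    """

    ids: tuple[str, ...]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic(self) -> np.ndarray:
        if len(self.ids) == 1:
            return np.zeros((1, 1))
        return squareform(sch.cophenet(self.linkage))

    def edge_lengths(self) -> np.ndarray:
        """Length of the edge from every node (leaf or internal) up to its parent.

        The two children of the merge at height h contribute (h - h_child)
        each, with leaf heights 0.  The root has no parent edge.  The sum of
        these lengths is the Petchey–Gaston functional diversity of the tree.
        """
        n = len(self.ids)
        Z = self.linkage
        node_height = np.concatenate([np.zeros(n), Z[:, 2]])
        lengths = []
        for k in range(Z.shape[0]):
            h = Z[k, 2]
            for child in (int(Z[k, 0]), int(Z[k, 1])):
                lengths.append(h - node_height[child])
        return np.asarray(lengths)

    def to_newick(self) -> str:
        n = len(self.ids)
        if n == 1:
            return f"{self.ids[0]}:0;"
        tree = sch.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


def upgma(d: DissimilarityMatrix) -> Dendrogram:
    """Average-linkage clustering of a dissimilarity matrix.

    Species are sorted lexicographically before clustering so that ties in
    the minimal pair distance are broken deterministically by label order.
    """
    if d.n < 2:
        raise ValidationError("UPGMA needs at least 2 species")
    order = sorted(range(d.n), key=lambda i: d.ids[i])
    ids = tuple(d.ids[i] for i in order)
    sub = d.values[np.ix_(order, order)]
    condensed = sub[np.triu_indices(d.n, k=1)]
    Z = sch.linkage(condensed, method="average")
    return Dendrogram(ids, Z)


def mst_edges(dist: np.ndarray) -> list[tuple[int, int, float]]:
    """Minimum spanning tree of a dense symmetric distance matrix (Prim).

    Returns S-1 edges (i, j, length).  Zero-length edges (duplicated points)
    are genuine edges and are kept.  Ties are broken by vertex index order,
    which is deterministic for a fixed row order.
    """
    n = dist.shape[0]
    if n < 2:
        raise ValidationError("minimum spanning tree needs at least 2 points")
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = dist[0].copy()
    best[0] = np.inf
    best_from = np.zeros(n, dtype=int)
    edges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        j = int(np.argmin(best))
        edges.append((int(best_from[j]), j, float(dist[best_from[j], j])))
        in_tree[j] = True
        best[j] = np.inf
        improved = dist[j] < best
        improved &= ~in_tree
        best[improved] = dist[j, improved]
        best_from[improved] = j
    return edges


def mst(coordinates: np.ndarray, ids: Sequence[str] | None = None):
    """Minimum spanning tree over points in trait space (Euclidean lengths).

    Returns a list of (label_i, label_j, length) with labels taken from
    ``ids`` (or integer indices if omitted).
    """
    pts = np.atleast_2d(np.asarray(coordinates, dtype=float))
    dist = cdist(pts, pts)
    edges = mst_edges(dist)
    if ids is None:
        return edges
    return [(ids[i], ids[j], w) for i, j, w in edges]
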