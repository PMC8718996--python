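"""Similarity-network construction from standardized behavioral profiles.

Subjects become nodes; an undirected edge joins two subjects whose behavioral
profiles are close in Euclidean distance.  Each node is linked to its R
nearest neighbors and the directed relation is symmetrized by union, giving a
sparse binary graph whose community structure can then be modelled.  The
default neighbor count follows the square-root-of-n heuristic common in
nearest-neighbor graph clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "SimilarityNetwork",
    "default_R",
    "pairwise_euclidean",
    "knn_graph",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise Euclidean distances between subjects."""

    d: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.isfinite(self.d).all():
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")
        if self.ids is None:
            self.ids = np.arange(self.d.shape[0])
        self.ids = np.asarray(self.ids)

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class SimilarityNetwork:
    """Undirected binary graph over subjects.

    Parameters
    ----------
    A : ndarray
        n x n symmetric 0/1 adjacency with zero diagonal.
    node_ids : array-like, optional
        Subject identifiers in node order.
    R : int, optional
        Neighbor count used to build the graph (None for graphs of other
        provenance, e.g. sampled from a block model).
    knn : bool
        True when the graph came from the union-symmetrized R-nearest-neighbor
        construction, in which case every degree is at least R.
    """

    A: np.ndarray
    node_ids: np.ndarray | None = None
    R: int | None = None
    knn: bool = False

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero (no self loops)")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        self.A = A.astype(np.uint8)
        if self.node_ids is None:
            self.node_ids = np.arange(A.shape[0])
        self.node_ids = np.asarray(self.node_ids)
        if self.knn and self.R is not None and self.n > 1:
            if self.degrees.min() < self.R:
                raise ValueError("kNN network has a node with degree < R")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.A.sum(axis=1).astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    @property
    def density(self) -> float:
        m = self.n * (self.n - 1) / 2
        return self.n_edges / m if m else 0.0

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (ei, ej) with ei < ej listing each undirected edge once."""
        ei, ej = np.nonzero(np.triu(self.A, 1))
        return ei.astype(np.int64), ej.astype(np.int64)

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.A)
        if self.node_ids is not None:
            nx.set_node_attributes(
                g, dict(enumerate(self.node_ids)), "subject_id")
        return g

    # -- text I/O --------------------------------------------------------
    def to_edgelist(self, path) -> None:
        """Write a whitespace-delimited edge list with an n/R header comment."""
        ei, ej = self.edges()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# sbmpheno edgelist n={self.n} R={self.R} knn={int(self.knn)}\n")
            for i, j in zip(ei, ej):
                fh.write(f"{i} {j}\n")

    @classmethod
    def from_edgelist(cls, path) -> "SimilarityNetwork":
        n = R = None
        knn = False
        edges = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("n="):
                            n = int(tok[2:])
                        elif tok.startswith("R=") and tok[2:] != "None":
                            R = int(tok[2:])
                        elif tok.startswith("knn="):
                            knn = bool(int(tok[4:]))
                    continue
                i, j = map(int, line.split()[:2])
                edges.append((i, j))
        if n is None:
            n = max(max(e) for e in edges) + 1 if edges else 0
        A = np.zeros((n, n), dtype=np.uint8)
        for i, j in edges:
            A[i, j] = A[j, i] = 1
        return cls(A=A, R=R, knn=knn)

    def to_dense_csv(self, path) -> None:
        np.savetxt(path, self.A, fmt="%d", delimiter=",")

    @classmethod
    def from_dense_csv(cls, path, **kw) -> "SimilarityNetwork":
        return cls(A=np.loadtxt(path, delimiter=",", dtype=int), **kw)


def default_R(n: int) -> int:
    """Square-root heuristic for the neighbor count: round(sqrt(n)), >= 1.

    For the 451-subject scale this gives 21 neighbors per node.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects to build a neighbor graph")
    return max(1, int(round(np.sqrt(n))))


def pairwise_euclidean(table) -> DistanceMatrix:
    """Euclidean distances between subjects over all measure columns.

    Accepts a :class:`~sbmpheno.cohort.BehavioralTable` or a plain n x p
    array.  A warning is issued for unstandardized tables: raw assay units
    dominate the metric arbitrarily.
    """
    ids = None
    if hasattr(table, "values") and hasattr(table, "standardized"):
        if not table.standardized:
            warnings.warn(
                "computing distances on an unstandardized table; site batch "
                "effects and assay units will distort the metric", stacklevel=2)
        x = table.values
        ids = table.subject_ids
    else:
        x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("expected an n x p matrix with p >= 1")
    if not np.isfinite(x).all():
        raise ValueError("measure matrix contains non-finite values")
    return DistanceMatrix(d=squareform(pdist(x, metric="euclidean")), ids=ids)


def knn_graph(dist: DistanceMatrix, R: int) -> SimilarityNetwork:
    """Union-symmetrized R-nearest-neighbor graph.

    Each node points to its R closest other nodes; the undirected edge set is
    the union of the directed relations, so A_ij = 1 when i is among j's R
    nearest or vice versa, and every degree is >= R.  Ties in distance are
    broken by the smaller node index so the construction is deterministic.
    """
    n = dist.n
    if not 1 <= R <= n - 1:
        raise ValueError(f"R must be in [1, n-1]; got R={R}, n={n}")
    d = dist.d.copy()
    np.fill_diagonal(d, np.inf)
    # stable mergesort on the distances keeps ascending-index order for ties
    order = np.argsort(d, axis=1, kind="stable")[:, :R]
    A = np.zeros((n, n), dtype=np.uint8)
    rows = np.repeat(np.arange(n), R)
    A[rows, order.ravel()] = 1
    A = np.maximum(A, A.T)
    return SimilarityNetwork(A=A, node_ids=dist.ids, R=R, knn=True)
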