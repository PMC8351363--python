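"""kNN hypergraphs and (hyper)graph Laplacians.

One hyperedge is grown around every vertex: the center plus its k most
similar other vertices under a kernel.  The hypergraph Laplacian

    L^h = I - D_v^{-1/2} H D_w D_e^{-1} H^T D_v^{-1/2}

is the standard positive semidefinite smoothness operator on hypergraphs;
for hyperedges of size two with unit weights it reduces to half the
normalized graph Laplacian of the induced graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dhrls.kernels import KernelMatrix


def _as_array(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


@dataclass
class Hypergraph:
    """Incidence matrix H (vertices x hyperedges) and hyperedge weights w."""

    H: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.H.ndim != 2:
            raise ValueError("incidence matrix must be 2-dimensional")
        if not np.isin(self.H, (0.0, 1.0)).all():
            raise ValueError("incidence matrix entries must be 0 or 1")
        if self.w.shape != (self.H.shape[1],):
            raise ValueError("one weight per hyperedge required")
        if np.any(self.w <= 0):
            raise ValueError("hyperedge weights must be positive")

    @property
    def n_vertices(self) -> int:
        return self.H.shape[0]

    @property
    def n_edges(self) -> int:
        return self.H.shape[1]

    @property
    def vertex_degrees(self) -> np.ndarray:
        """d(v): number of hyperedges containing each vertex."""
        return self.H.sum(axis=1)

    @property
    def edge_degrees(self) -> np.ndarray:
        """delta(e): number of vertices in each hyperedge."""
        return self.H.sum(axis=0)


@dataclass
class LaplacianMatrix:
    """Symmetric PSD regularizer matrix, hypergraph- or graph-flavored."""

    values: np.ndarray
    flavor: str = "hypergraph"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.values = 0.5 * (self.values + self.values.T)


def build_knn_hypergraph(
    K, k: int, normalize_weights: bool = True
) -> Hypergraph:
    """One hyperedge per vertex: the center plus its k nearest neighbors.

    Neighbors are the k other vertices with the largest similarity to the
    center (self-similarity excluded; ties broken by lower index).  The
    hyperedge weight is the sum of the k neighbor similarities; weights are
    divided by their total when ``normalize_weights`` is set.
    """
    V = _as_array(K)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("kernel must be square")
    N = V.shape[0]
    if not 1 <= k <= N - 1:
        raise ValueError(f"k must be in [1, {N - 1}], got {k}")
    H = np.zeros((N, N))
    w = np.zeros(N)
    for j in range(N):
        sims = V[:, j].copy()
        sims[j] = -np.inf  # center never its own neighbor
        # stable argsort descending -> ties broken by lower index
        order = np.argsort(-sims, kind="stable")
        neighbors = order[:k]
        H[j, j] = 1.0
        H[neighbors, j] = 1.0
        w[j] = V[neighbors, j].sum()
    if np.any(w <= 0):
        # degenerate all-zero similarity columns: fall back to uniform weight
        w = np.where(w > 0, w, w[w > 0].min() if np.any(w > 0) else 1.0)
    if normalize_weights:
        w = w / w.sum()
    return Hypergraph(H=H, w=w)


def hypergraph_laplacian(G: Hypergraph) -> LaplacianMatrix:
    """L^h = I - D_v^{-1/2} H D_w D_e^{-1} H^T D_v^{-1/2}."""
    d_v = G.vertex_degrees
    d_e = G.edge_degrees
    if np.any(d_v == 0):
        raise ValueError("isolated vertex (degree 0) in hypergraph")
    if np.any(d_e == 0):
        raise ValueError("empty hyperedge in hypergraph")
    inv_sqrt_dv = 1.0 / np.sqrt(d_v)
    Hw = G.H * (G.w / d_e)[None, :]
    theta = inv_sqrt_dv[:, None] * (Hw @ G.H.T) * inv_sqrt_dv[None, :]
    return LaplacianMatrix(np.eye(G.n_vertices) - theta, flavor="hypergraph")


def graph_laplacian(K, symmetric: bool = True) -> LaplacianMatrix:
    """Normalized graph Laplacian of a similarity matrix.

    ``L = D^{-1/2} (D - K) D^{-1/2}`` with ``D(k,k) = sum_l K(k,l)``.
    The non-symmetric variant ``D^{-1/2} (D - K) D^{1/2}`` is available
    behind ``symmetric=False`` for fidelity experiments only; it is not PSD
    and not used by the solver.
    """
    V = _as_array(K)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("kernel must be square")
    d = V.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("zero or negative row sum in similarity matrix")
    delta = np.diag(d) - V
    inv_sqrt = 1.0 / np.sqrt(d)
    if symmetric:
        values = inv_sqrt[:, None] * delta * inv_sqrt[None, :]
        return LaplacianMatrix(values, flavor="normalized_graph")
    values = inv_sqrt[:, None] * delta * np.sqrt(d)[None, :]
    lap = LaplacianMatrix.__new__(LaplacianMatrix)
    lap.values = values  # deliberately not symmetrized
    lap.flavor = "normalized_graph_asymmetric"
    return lap
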