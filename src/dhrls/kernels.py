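"""Per-side similarity kernels for bipartite link prediction.

Four builders mirroring the usual information sources:

* Gaussian interaction profile (GIP) kernel on rows/columns of the
  adjacency matrix, ``exp(-gamma * ||y_i - y_j||^2)``.
* Semantic similarity over a term DAG (e.g. a disease ontology) with a
  per-level contribution decay ``delta``.
* Cosine similarity of per-entity feature vectors (e.g. network topology
  features from a protein-protein interaction graph).
* Normalization of a raw pairwise alignment-score matrix (e.g.
  Smith-Waterman scores) to unit self-similarity.

Kernels computed by external tools (GO semantic similarity etc.) enter the
pipeline as precomputed :class:`KernelMatrix` objects via
:func:`dhrls.netio.read_kernel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from dhrls.netio import AssociationMatrix

_SYM_TOL = 1e-10


@dataclass
class KernelMatrix:
    """Square symmetric similarity matrix over one side's entities."""

    values: np.ndarray
    entity_ids: list[str] = field(default_factory=list)
    name: str = "kernel"
    side: str = "disease"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not self.entity_ids:
            self.entity_ids = [f"e{i}" for i in range(self.values.shape[0])]
        self.entity_ids = [str(e) for e in self.entity_ids]
        if len(self.entity_ids) != self.values.shape[0]:
            raise ValueError("entity_ids length does not match matrix shape")
        if self.side not in ("disease", "gene"):
            raise ValueError(f"side must be 'disease' or 'gene', got {self.side!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel contains non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-8:
            raise ValueError("kernel matrix is not symmetric")
        # enforce exact symmetry for downstream eigen/solve stability
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class DiseaseDag:
    """A term DAG given as child->parent edges, for semantic similarity.

    ``delta`` is the semantic contribution factor: each step from a term up
    to an ancestor multiplies its contribution by ``delta`` (default 0.5).
    """

    nodes: list[str]
    parent_edges: list[tuple[str, str]]
    delta: float = 0.5

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        self.parent_edges = [(str(c), str(p)) for c, p in self.parent_edges]
        if not 0 < self.delta <= 1:
            raise ValueError("delta must be in (0, 1]")
        known = set(self.nodes)
        for c, p in self.parent_edges:
            if c not in known or p not in known:
                raise ValueError(f"edge ({c!r}, {p!r}) references unknown node")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent edges contain a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with edges child -> parent."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.parent_edges)
        return g


@dataclass
class FeatureTable:
    """Per-entity feature vectors (rows) for cosine similarity."""

    vectors: np.ndarray
    entity_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.size == 0:
            raise ValueError("empty feature table")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("features contain non-finite entries")
        if not self.entity_ids:
            self.entity_ids = [f"e{i}" for i in range(self.vectors.shape[0])]
        if len(self.entity_ids) != self.vectors.shape[0]:
            raise ValueError("entity_ids length does not match vector count")


@dataclass
class RawScoreMatrix:
    """Raw pairwise alignment scores with strictly positive self-scores."""

    values: np.ndarray
    entity_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("score matrix must be square")
        if np.any(np.diag(self.values) <= 0):
            raise ValueError("self-scores must be strictly positive")
        if not self.entity_ids:
            self.entity_ids = [f"e{i}" for i in range(self.values.shape[0])]
        if len(self.entity_ids) != self.values.shape[0]:
            raise ValueError("entity_ids length does not match matrix shape")


def gip_kernel(
    Y: AssociationMatrix, side: str = "disease", gamma: float = 0.5
) -> KernelMatrix:
    """Gaussian interaction profile kernel on association profiles.

    ``K(i, j) = exp(-gamma * ||y_i - y_j||^2)`` where ``y_i`` is row i of Y
    (``side="disease"``) or column i (``side="gene"``). The bandwidth is an
    absolute value, 0.5 by default.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if side == "disease":
        profiles, ids = Y.values, Y.row_ids
    elif side == "gene":
        profiles, ids = Y.values.T, Y.col_ids
    else:
        raise ValueError(f"side must be 'disease' or 'gene', got {side!r}")
    # binary profiles: ||y_i - y_j||^2 = n_i + n_j - 2 <y_i, y_j>
    gram = profiles @ profiles.T
    norms = np.diag(gram)
    sq_dist = np.maximum(norms[:, None] + norms[None, :] - 2.0 * gram, 0.0)
    values = np.exp(-gamma * sq_dist)
    return KernelMatrix(values, list(ids), name="GIP", side=side)


def _semantic_scores(dag: DiseaseDag, d: str, children: dict[str, list[str]],
                     ancestors: dict[str, set[str]]) -> dict[str, float]:
    """Contribution of each ancestor term t to disease d: delta per level,
    maximized over descent paths inside d's ancestor closure."""
    T_d = ancestors[d]
    scores: dict[str, float] = {}

    def score(t: str) -> float:
        if t in scores:
            return scores[t]
        if t == d:
            val = 1.0
        else:
            kids = [c for c in children.get(t, ()) if c in T_d]
            val = dag.delta * max(score(c) for c in kids)
        scores[t] = val
        return val

    for t in T_d:
        score(t)
    return scores


def semantic_kernel(
    dag: DiseaseDag, targets: Sequence[str] | None = None
) -> KernelMatrix:
    """DAG-based semantic similarity kernel over ``targets``.

    For each target d the ancestor closure T_d (d plus all its ancestors)
    receives contributions D_d(t): 1 at d itself, and delta times the best
    child contribution for every proper ancestor. The similarity of two
    targets is the shared contribution mass normalized by the total:

        K(d_i, d_j) = sum_{t in T_i ∩ T_j} (D_i(t) + D_j(t)) / (DV_i + DV_j)

    with DV = sum of all contributions; K(d, d) = 1 by construction.
    """
    if targets is None:
        targets = dag.nodes
    targets = [str(t) for t in targets]
    node_set = set(dag.nodes)
    for t in targets:
        if t not in node_set:
            raise ValueError(f"unknown target node: {t!r}")

    g = dag.to_networkx()
    # ancestor closure: nodes reachable along child->parent edges, incl. self
    ancestors = {t: nx.descendants(g, t) | {t} for t in targets}
    children: dict[str, list[str]] = {}
    for c, p in dag.parent_edges:
        children.setdefault(p, []).append(c)

    scores = {t: _semantic_scores(dag, t, children, ancestors) for t in targets}
    dv = {t: sum(scores[t].values()) for t in targets}

    N = len(targets)
    values = np.eye(N)
    for i in range(N):
        for j in range(i + 1, N):
            a, b = targets[i], targets[j]
            shared = ancestors[a] & ancestors[b]
            if shared:
                num = sum(scores[a][t] + scores[b][t] for t in shared)
                values[i, j] = values[j, i] = num / (dv[a] + dv[b])
    return KernelMatrix(values, targets, name="SEM", side="disease")


def cosine_kernel(features: FeatureTable) -> KernelMatrix:
    """Cosine similarity of per-entity feature vectors.

    A zero vector has similarity 0 to every other entity and 1 to itself,
    keeping the diagonal at unity without dividing by zero.
    """
    X = features.vectors
    norms = np.linalg.norm(X, axis=1)
    if np.all(norms == 0):
        raise ValueError("at least one feature vector must be nonzero")
    safe = np.where(norms > 0, norms, 1.0)
    values = (X / safe[:, None]) @ (X / safe[:, None]).T
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, -1.0, 1.0)
    return KernelMatrix(values, list(features.entity_ids), name="COS", side="gene")


def normalized_sw_kernel(raw: RawScoreMatrix) -> KernelMatrix:
    """Normalize raw alignment scores to ``s_ij / sqrt(s_ii * s_jj)``.

    The result has unit diagonal and is symmetrized as (K + K^T)/2 to absorb
    any asymmetry in the supplied raw scores.
    """
    s = raw.values
    d = np.sqrt(np.diag(s))
    values = s / np.outer(d, d)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(values, list(raw.entity_ids), name="SW", side="gene")
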