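"""Synthetic bipartite networks with planted co-cluster structure.

The generator emulates the inputs of a real study end to end: a binary
association matrix with planted disease-gene blocks plus label noise, a term
DAG whose subtrees follow the disease blocks (feeding the semantic kernel),
noisy block-indicator feature vectors per gene (feeding the cosine kernel),
and GIP kernels from the clean matrix.  Cluster structure is used, rather
than generic low-rank structure, because both the kNN hypergraph and CKA
respond to it, so every pipeline stage is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dhrls.kernels import (
    DiseaseDag,
    FeatureTable,
    KernelMatrix,
    cosine_kernel,
    gip_kernel,
    semantic_kernel,
)
from dhrls.mkl import KernelBundle
from dhrls.netio import AssociationMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    Defaults plant four balanced co-clusters in an 80x80 network with dense
    within-block edges (0.85), sparse background (0.05), and 2% label flips
    - a clearly recoverable but non-trivial signal.
    """

    n: int = 80
    m: int = 80
    n_blocks: int = 4
    density_in: float = 0.85
    density_out: float = 0.05
    flip_noise: float = 0.02
    feature_dim: int = 8
    feature_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.density_out < self.density_in <= 1):
            raise ValueError("require 0 <= density_out < density_in <= 1")
        if not 0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must be in [0, 0.5)")
        if self.n < 1 or self.m < 1 or self.n_blocks < 1:
            raise ValueError("n, m, n_blocks must be positive")
        if self.n_blocks > min(self.n, self.m):
            raise ValueError("more blocks than entities on a side")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be at least 1")


@dataclass
class SyntheticData:
    """Everything the generator plants, bundled for downstream use."""

    Y: AssociationMatrix
    disease_bundle: KernelBundle
    gene_bundle: KernelBundle
    disease_blocks: np.ndarray
    gene_blocks: np.ndarray
    dag: DiseaseDag
    gene_features: FeatureTable

    @property
    def disease_side_kernels(self) -> list[KernelMatrix]:
        """Side-information kernels (GIP excluded) for leak-free CV."""
        return [K for K in self.disease_bundle.kernels if K.name != "GIP"]

    @property
    def gene_side_kernels(self) -> list[KernelMatrix]:
        return [K for K in self.gene_bundle.kernels if K.name != "GIP"]


def _balanced_blocks(count: int, n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.arange(count) % n_blocks
    rng.shuffle(labels)
    return labels


def _block_dag(disease_ids: list[str], blocks: np.ndarray, n_blocks: int) -> DiseaseDag:
    """Star-of-subtrees DAG: root -> one node per block -> member diseases."""
    nodes = ["root"] + [f"block{b}" for b in range(n_blocks)] + list(disease_ids)
    edges = [(f"block{b}", "root") for b in range(n_blocks)]
    edges += [(d, f"block{blocks[i]}") for i, d in enumerate(disease_ids)]
    return DiseaseDag(nodes=nodes, parent_edges=edges)


def _block_features(
    blocks: np.ndarray, dim: int, noise: float, rng: np.random.Generator
) -> np.ndarray:
    n_blocks = blocks.max() + 1
    X = np.zeros((len(blocks), max(dim, n_blocks)))
    X[np.arange(len(blocks)), blocks] = 1.0
    X = X[:, :dim] if dim >= n_blocks else X[:, :n_blocks]
    return X + noise * rng.standard_normal(X.shape)


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw a reproducible planted-structure dataset from ``spec``.

    Diseases and genes are assigned to balanced blocks; an edge is drawn
    with probability ``density_in`` when blocks match and ``density_out``
    otherwise, then each label is flipped with probability ``flip_noise``.
    """
    rng = np.random.default_rng(spec.seed)
    d_blocks = _balanced_blocks(spec.n, spec.n_blocks, rng)
    g_blocks = _balanced_blocks(spec.m, spec.n_blocks, rng)
    probs = np.where(
        d_blocks[:, None] == g_blocks[None, :], spec.density_in, spec.density_out
    )
    Yv = (rng.random((spec.n, spec.m)) < probs).astype(float)
    if spec.flip_noise:
        flips = rng.random((spec.n, spec.m)) < spec.flip_noise
        Yv = np.where(flips, 1.0 - Yv, Yv)

    row_ids = [f"d{i}" for i in range(spec.n)]
    col_ids = [f"g{j}" for j in range(spec.m)]
    Y = AssociationMatrix(Yv, row_ids, col_ids)

    dag = _block_dag(row_ids, d_blocks, spec.n_blocks)
    K_sem = semantic_kernel(dag, targets=row_ids)
    features = FeatureTable(
        _block_features(g_blocks, spec.feature_dim, spec.feature_noise, rng),
        entity_ids=col_ids,
    )
    K_cos = cosine_kernel(features)

    disease_bundle = KernelBundle([K_sem, gip_kernel(Y, side="disease")])
    gene_bundle = KernelBundle([K_cos, gip_kernel(Y, side="gene")])
    return SyntheticData(
        Y=Y,
        disease_bundle=disease_bundle,
        gene_bundle=gene_bundle,
        disease_blocks=d_blocks,
        gene_blocks=g_blocks,
        dag=dag,
        gene_features=features,
    )


def make_worked_example() -> dict:
    """Small hand-checkable fixtures used across the docs and test suite.

    Returns a dict with:

    * ``scalar``: the 1x1 instance (K=1, Y=1, lambda=0, beta=1) whose
      alternating updates contract to alpha_d = alpha_g = 2/3, F* = 2/3.
    * ``sibling_dag``: two sibling terms under one parent; semantic
      similarity 1/3 at delta = 0.5.
    * ``network_rows``: six published (|V|, |W|, |E|) benchmark-network
      triples with their link density / average degree statistics.
    * ``als_instance``: a fixed 4x3 instance (lambda=0) with the joint
      ridge minimizer computed from the stacked normal equations, the
      reference the alternating solver must reach.
    """
    rng = np.random.default_rng(20210809)
    n, m = 4, 3
    Yv = (rng.random((n, m)) < 0.5).astype(float)
    A = rng.standard_normal((n, n))
    Kd = A @ A.T / n + np.eye(n)
    B = rng.standard_normal((m, m))
    Kg = B @ B.T / m + np.eye(m)
    beta = 1.0
    # stacked joint ridge: unknowns x = [vec(alpha_d); vec(G)], G = alpha_g^T
    C = np.hstack([np.kron(np.eye(m), Kd), np.kron(Kg, np.eye(n))])
    x = np.linalg.solve(C.T @ C + beta * np.eye(2 * n * m), 2.0 * C.T @ Yv.ravel(order="F"))
    alpha_d = x[: n * m].reshape((n, m), order="F")
    alpha_g = x[n * m :].reshape((n, m), order="F").T

    return {
        "scalar": {
            "K": np.array([[1.0]]),
            "Y": np.array([[1.0]]),
            "beta": 1.0,
            "expected_alpha": 2.0 / 3.0,
            "expected_F": 2.0 / 3.0,
        },
        "sibling_dag": {
            "dag": DiseaseDag(
                nodes=["p", "a", "b"], parent_edges=[("a", "p"), ("b", "p")]
            ),
            "targets": ["a", "b"],
            "expected_similarity": 1.0 / 3.0,
            "expected_dv": 1.5,
        },
        "network_rows": [
            # name, |V|, |W|, |E|, LD, AD, LAD, RAD (published statistics)
            ("GPC", 95, 223, 635, 0.0300, 2.00, 6.68, 2.85),
            ("Enzymes", 664, 445, 2926, 0.0099, 2.64, 4.41, 6.58),
            ("Ionchannel", 210, 204, 1476, 0.0345, 3.57, 7.03, 7.24),
            ("Drug-target", 200, 150, 454, 0.0151, 1.30, 2.27, 3.03),
            ("SW", 18, 14, 89, 0.3532, 2.78, 4.94, 6.36),
            ("CO", 144, 151, 12170, 0.5597, 41.25, 84.51, 80.60),
        ],
        "als_instance": {
            "Y": Yv,
            "K_d": Kd,
            "K_g": Kg,
            "beta": beta,
            "expected_alpha_d": alpha_d,
            "expected_alpha_g": alpha_g,
        },
    }
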