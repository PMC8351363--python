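"""Centered kernel alignment (CKA) multiple kernel learning.

Combines a list of same-side kernels into a single kernel
``K* = sum_i w_i K_i`` with simplex-constrained weights chosen to maximize
the alignment (Frobenius cosine) between the centered combined kernel and an
ideal, label-derived kernel (Y Y^T on the row side, Y^T Y on the column
side). The maximization reduces to the convex quadratic program

    min_{w >= 0, sum w = 1}  w^T M w - 2 w^T a

with ``M_ij = <K_i^c, K_j^c>_F`` and ``a_i = <K_i^c, K_ideal>_F`` where the
superscript c denotes double centering.  With few kernels the QP is solved
exactly by enumerating active sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from dhrls.kernels import KernelMatrix
from dhrls.netio import AssociationMatrix

_WEIGHT_SNAP = 1e-10


@dataclass
class KernelBundle:
    """Ordered list of same-side kernels, optionally with solved weights."""

    kernels: list[KernelMatrix]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("bundle must contain at least one kernel")
        shape = self.kernels[0].values.shape
        ids = self.kernels[0].entity_ids
        for K in self.kernels[1:]:
            if K.values.shape != shape:
                raise ValueError("bundle kernels differ in shape")
            if K.entity_ids != ids:
                raise ValueError("bundle kernels differ in entity ids")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.kernels),):
                raise ValueError("weights length does not match kernel count")
            if np.any(self.weights < -1e-10) or abs(self.weights.sum() - 1) > 1e-8:
                raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def names(self) -> list[str]:
        return [K.name for K in self.kernels]

    def __len__(self) -> int:
        return len(self.kernels)


@dataclass
class CkaProblem:
    """Quadratic program data for the alignment maximization."""

    M: np.ndarray
    a: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def objective(self, w: np.ndarray) -> float:
        w = np.asarray(w, dtype=float)
        return float(w @ self.M @ w - 2.0 * w @ self.a)


def center_kernel(K: KernelMatrix) -> KernelMatrix:
    """Double-center a kernel: K^c = U K U with U = I - (1/N) 11^T.

    Every row and column of the result sums to zero; centering is
    idempotent.
    """
    V = K.values
    row_means = V.mean(axis=0, keepdims=True)
    col_means = V.mean(axis=1, keepdims=True)
    centered = V - row_means - col_means + V.mean()
    return KernelMatrix(centered, list(K.entity_ids), name=K.name, side=K.side)


def alignment(K1, K2) -> float:
    """Frobenius cosine similarity between two kernel matrices, in [-1, 1]."""
    A = K1.values if isinstance(K1, KernelMatrix) else np.asarray(K1, dtype=float)
    B = K2.values if isinstance(K2, KernelMatrix) else np.asarray(K2, dtype=float)
    if A.shape != B.shape:
        raise ValueError("kernels must share shape")
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        raise ValueError("alignment undefined for zero-norm kernel")
    return float(np.sum(A * B) / (na * nb))


def ideal_kernel(Y: AssociationMatrix, side: str = "disease") -> KernelMatrix:
    """Label-space kernel from training associations only.

    ``Y Y^T`` over rows (disease side) or ``Y^T Y`` over columns (gene
    side); symmetric positive semidefinite by construction.
    """
    if side == "disease":
        values, ids = Y.values @ Y.values.T, Y.row_ids
    elif side == "gene":
        values, ids = Y.values.T @ Y.values, Y.col_ids
    else:
        raise ValueError(f"side must be 'disease' or 'gene', got {side!r}")
    return KernelMatrix(values, list(ids), name="ideal", side=side)


def _solve_simplex_qp(M: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Exact minimizer of w^T M w - 2 w^T a on the probability simplex.

    Enumerates candidate supports: for each nonempty subset S the
    equality-constrained KKT system on S is solved; the feasible candidate
    with the smallest objective is returned.  Exact for convex M and cheap
    for the handful of kernels used per side.
    """
    k = M.shape[0]
    M = M + 1e-12 * np.trace(M) * np.eye(k) if np.trace(M) > 0 else M + 1e-12 * np.eye(k)
    best_w, best_obj = None, np.inf
    for size in range(1, k + 1):
        for S in combinations(range(k), size):
            idx = np.array(S)
            # KKT: 2 M_SS x + nu 1 = 2 a_S ; 1^T x = 1
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = 2.0 * M[np.ix_(idx, idx)]
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.concatenate([2.0 * a[idx], [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            x = sol[:size]
            if np.any(x < -1e-9):
                continue
            w = np.zeros(k)
            w[idx] = np.clip(x, 0.0, None)
            w /= w.sum()
            obj = float(w @ M @ w - 2.0 * w @ a)
            if obj < best_obj - 1e-15:
                best_obj, best_w = obj, w
    assert best_w is not None, "simplex QP must be feasible"
    return best_w


def build_cka_problem(
    bundle: KernelBundle, ideal: KernelMatrix, center_ideal: bool = False
) -> CkaProblem:
    """Assemble the QP data (M, a) from centered candidate kernels."""
    target = center_kernel(ideal).values if center_ideal else ideal.values
    if np.linalg.norm(target) == 0:
        raise ValueError("ideal kernel has zero norm (no training associations?)")
    centered = [center_kernel(K).values for K in bundle.kernels]
    k = len(centered)
    M = np.empty((k, k))
    a = np.empty(k)
    for i in range(k):
        a[i] = np.sum(centered[i] * target)
        for j in range(i, k):
            M[i, j] = M[j, i] = np.sum(centered[i] * centered[j])
    return CkaProblem(M=M, a=a)


def solve_weights(
    bundle: KernelBundle, ideal: KernelMatrix, center_ideal: bool = False
) -> np.ndarray:
    """CKA-optimal simplex weights for the bundle against the ideal kernel.

    Tiny weights (< 1e-10, QP slack) are snapped to zero and the vector
    renormalized. The solved weights are also stored on the bundle.
    """
    problem = build_cka_problem(bundle, ideal, center_ideal=center_ideal)
    w = _solve_simplex_qp(problem.M, problem.a)
    w[w < _WEIGHT_SNAP] = 0.0
    w /= w.sum()
    bundle.weights = w
    return w


def combine(bundle: KernelBundle) -> KernelMatrix:
    """Weighted sum of the (uncentered) member kernels at the solved weights."""
    if bundle.weights is None:
        raise ValueError("bundle weights are not solved; call solve_weights first")
    values = np.tensordot(bundle.weights, [K.values for K in bundle.kernels], axes=1)
    first = bundle.kernels[0]
    return KernelMatrix(values, list(first.entity_ids), name="combined", side=first.side)


def mean_combine(bundle: KernelBundle) -> KernelMatrix:
    """Uniform-weight combination (mean-weighted baseline)."""
    k = len(bundle.kernels)
    bundle.weights = np.full(k, 1.0 / k)
    return combine(bundle)
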