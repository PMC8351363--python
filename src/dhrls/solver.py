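"""Alternating least-squares fitting of DHRLS and its baselines.

The model scores every (row-entity, column-entity) pair from two coefficient
matrices, one per side, tied together through a shared residual:

    E = || K_d a_d + (K_g a_g)^T - 2 Y ||_F^2
        + lam_d tr(a_d^T K_d L_d K_d a_d) + lam_g tr(a_g^T K_g L_g K_g a_g)
        + beta (||a_d||_F^2 + ||a_g||_F^2)

with L the hypergraph Laplacian (DHRLS), the normalized graph Laplacian
(DGRLS), or absent.  Each block update is the exact minimizer of a convex
quadratic, so the objective never increases.  Predictions are
F* = (K_d a_d + (K_g a_g)^T) / 2.

The single-side LapRLS baseline F = K (K + lam L K)^{-1} Y is provided for
comparison.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from dhrls.hypergraph import (
    LaplacianMatrix,
    build_knn_hypergraph,
    graph_laplacian,
    hypergraph_laplacian,
)
from dhrls.kernels import KernelMatrix
from dhrls.netio import AssociationMatrix


@dataclass
class SolverParams:
    """Hyperparameters of the alternating solver.

    Defaults are the values selected on the gene-disease benchmark:
    lambda_d=1, lambda_g=0.25, beta=1, 50 hypergraph neighbors, 10
    alternating rounds.
    """

    lambda_d: float = 1.0
    lambda_g: float = 0.25
    beta: float = 1.0
    knn_k: int = 50
    n_iter: int = 10
    regularizer: str = "hypergraph"  # hypergraph | graph | none
    tol: float | None = None  # optional relative-objective early stop

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.lambda_d < 0 or self.lambda_g < 0:
            raise ValueError("lambda_d and lambda_g must be nonnegative")
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")
        if self.regularizer not in ("hypergraph", "graph", "none"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")


@dataclass
class DhrlsModel:
    """Fitted coefficients plus the kernels/Laplacians used to fit them."""

    alpha_d: np.ndarray
    alpha_g: np.ndarray
    K_d: np.ndarray
    K_g: np.ndarray
    L_d: np.ndarray
    L_g: np.ndarray
    params: SolverParams
    objective_trace: list[float] = field(default_factory=list)
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)


def _arr(X) -> np.ndarray:
    if isinstance(X, AssociationMatrix):
        return X.values
    if isinstance(X, KernelMatrix):
        return X.values
    if isinstance(X, LaplacianMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _spd_solve(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B for symmetric positive definite A, with a lstsq fallback."""
    try:
        c, low = scipy.linalg.cho_factor(A, check_finite=False)
        return scipy.linalg.cho_solve((c, low), B, check_finite=False)
    except scipy.linalg.LinAlgError:
        return np.linalg.lstsq(A, B, rcond=None)[0]


def objective(model: DhrlsModel, Y, params: SolverParams | None = None) -> float:
    """Value of the regularized least-squares objective at the model state."""
    params = params or model.params
    Yv = _arr(Y)
    K_d, K_g = model.K_d, model.K_g
    a_d, a_g = model.alpha_d, model.alpha_g
    if K_d.shape[0] != Yv.shape[0] or K_g.shape[0] != Yv.shape[1]:
        raise ValueError("kernel shapes do not match the association matrix")
    resid = K_d @ a_d + (K_g @ a_g).T - 2.0 * Yv
    val = float(np.sum(resid**2))
    if params.lambda_d:
        Kd_ad = K_d @ a_d
        val += params.lambda_d * float(np.sum(Kd_ad * (model.L_d @ Kd_ad)))
    if params.lambda_g:
        Kg_ag = K_g @ a_g
        val += params.lambda_g * float(np.sum(Kg_ag * (model.L_g @ Kg_ag)))
    val += params.beta * float(np.sum(a_d**2) + np.sum(a_g**2))
    return val


def _system_matrix(K: np.ndarray, L: np.ndarray, lam: float, beta: float) -> np.ndarray:
    A = K @ K + beta * np.eye(K.shape[0])
    if lam:
        A = A + lam * K @ L @ K
    return A


def update_alpha_d(model: DhrlsModel, Y, params: SolverParams | None = None) -> np.ndarray:
    """Exact minimizer over alpha_d with alpha_g held fixed."""
    params = params or model.params
    Yv = _arr(Y)
    K_d, K_g = model.K_d, model.K_g
    A = _system_matrix(K_d, model.L_d, params.lambda_d, params.beta)
    rhs = 2.0 * K_d @ Yv - K_d @ model.alpha_g.T @ K_g
    return _spd_solve(A, rhs)


def update_alpha_g(model: DhrlsModel, Y, params: SolverParams | None = None) -> np.ndarray:
    """Exact minimizer over alpha_g with alpha_d held fixed."""
    params = params or model.params
    Yv = _arr(Y)
    K_d, K_g = model.K_d, model.K_g
    A = _system_matrix(K_g, model.L_g, params.lambda_g, params.beta)
    rhs = 2.0 * K_g @ Yv.T - K_g @ model.alpha_d.T @ K_d
    return _spd_solve(A, rhs)


def build_regularizer(K: np.ndarray, params: SolverParams) -> np.ndarray:
    """Side Laplacian from the combined kernel, per the chosen regularizer.

    The hypergraph neighbor count is capped at N-1 so small problems remain
    well-posed under the default grid value.
    """
    N = K.shape[0]
    if params.regularizer == "none":
        return np.zeros((N, N))
    if params.regularizer == "graph":
        return graph_laplacian(K).values
    k = min(params.knn_k, N - 1)
    if k < 1:
        raise ValueError("kernel too small for a hypergraph (need N >= 2)")
    return hypergraph_laplacian(build_knn_hypergraph(K, k)).values


def fit(
    Y,
    K_d,
    K_g,
    params: SolverParams | None = None,
    L_d=None,
    L_g=None,
) -> DhrlsModel:
    """Alternating least-squares fit.

    alpha_g starts at zero (the first alpha_d update is then a pure kernel
    ridge fit); alpha_d and alpha_g are updated in turn for ``n_iter``
    rounds, recording the objective after every half-step.  ``L_d``/``L_g``
    override the Laplacians built from the combined kernels.
    """
    params = params or SolverParams()
    Yv = _arr(Y)
    Kd, Kg = _arr(K_d), _arr(K_g)
    n, m = Yv.shape
    if Kd.shape != (n, n) or Kg.shape != (m, m):
        raise ValueError("kernel shapes do not match the association matrix")
    Ld = _arr(L_d) if L_d is not None else build_regularizer(Kd, params)
    Lg = _arr(L_g) if L_g is not None else build_regularizer(Kg, params)

    row_ids = Y.row_ids if isinstance(Y, AssociationMatrix) else []
    col_ids = Y.col_ids if isinstance(Y, AssociationMatrix) else []
    model = DhrlsModel(
        alpha_d=np.zeros((n, m)),
        alpha_g=np.zeros((m, n)),
        K_d=Kd,
        K_g=Kg,
        L_d=Ld,
        L_g=Lg,
        params=params,
        row_ids=list(row_ids),
        col_ids=list(col_ids),
    )
    prev = objective(model, Yv, params)
    for _ in range(params.n_iter):
        model.alpha_d = update_alpha_d(model, Yv, params)
        model.objective_trace.append(objective(model, Yv, params))
        model.alpha_g = update_alpha_g(model, Yv, params)
        current = objective(model, Yv, params)
        model.objective_trace.append(current)
        if params.tol is not None and prev > 0:
            if abs(prev - current) / max(prev, 1e-300) < params.tol:
                break
        prev = current
    return model


def predict(model: DhrlsModel) -> np.ndarray:
    """Prediction scores F* = (K_d a_d + (K_g a_g)^T) / 2."""
    if model.alpha_d is None or model.alpha_g is None:
        raise ValueError("model is not fitted")
    return 0.5 * (model.K_d @ model.alpha_d + (model.K_g @ model.alpha_g).T)


def fit_laprls(Y, K, side: str = "disease", lam: float = 1.0) -> np.ndarray:
    """Single-side Laplacian regularized least squares baseline.

    F = K (K + lam L K)^{-1} Y with L the normalized graph Laplacian of K
    (row side), or the transposed analogue on the column side.
    """
    Yv = _arr(Y)
    Kv = _arr(K)
    target = Yv if side == "disease" else Yv.T
    if side not in ("disease", "gene"):
        raise ValueError(f"side must be 'disease' or 'gene', got {side!r}")
    if Kv.shape[0] != target.shape[0]:
        raise ValueError("kernel does not match association matrix side")
    L = graph_laplacian(Kv).values if lam else np.zeros_like(Kv)
    A = Kv + lam * L @ Kv
    alpha = np.linalg.solve(A, target)
    F = Kv @ alpha
    return F if side == "disease" else F.T


def fit_laprls_combined(Y, K_d, K_g, lam_d: float = 1.0, lam_g: float = 1.0) -> np.ndarray:
    """Average of the two single-side LapRLS predictions."""
    Fa = fit_laprls(Y, K_d, side="disease", lam=lam_d)
    Fb = fit_laprls(Y, K_g, side="gene", lam=lam_g)
    return 0.5 * (Fa + Fb)


def save_model(model: DhrlsModel, path) -> None:
    """Persist a fitted model as a zip of .npy arrays plus a JSON block."""
    path = Path(path)
    import io as _io

    with zipfile.ZipFile(path, "w") as zf:
        for name in ("alpha_d", "alpha_g", "K_d", "K_g", "L_d", "L_g"):
            buf = _io.BytesIO()
            np.save(buf, getattr(model, name))
            zf.writestr(f"{name}.npy", buf.getvalue())
        meta = {
            "params": vars(model.params),
            "objective_trace": model.objective_trace,
            "row_ids": model.row_ids,
            "col_ids": model.col_ids,
        }
        zf.writestr("meta.json", json.dumps(meta))


def load_model(path) -> DhrlsModel:
    """Inverse of :func:`save_model`."""
    import io as _io

    with zipfile.ZipFile(Path(path)) as zf:
        arrays = {
            name: np.load(_io.BytesIO(zf.read(f"{name}.npy")))
            for name in ("alpha_d", "alpha_g", "K_d", "K_g", "L_d", "L_g")
        }
        meta = json.loads(zf.read("meta.json"))
    return DhrlsModel(
        params=SolverParams(**meta["params"]),
        objective_trace=list(meta["objective_trace"]),
        row_ids=meta["row_ids"],
        col_ids=meta["col_ids"],
        **arrays,
    )
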