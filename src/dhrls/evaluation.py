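"""Cross-validation protocols, ranking metrics, and grid search.

Two protocols are supported:

* CV1 (pair holdout): the observed associations are partitioned into folds;
  each fold's held-out 1-entries are zeroed in the training matrix and
  ranked against every 0-cell of the matrix.
* CV2 (cold start): whole rows (diseases) are partitioned; a test fold's
  rows are zeroed entirely in training, so nothing about the held-out
  entities' associations leaks into the GIP or ideal kernels, which are
  always rebuilt from the masked training matrix.

AUC is the Mann-Whitney probability that a random positive outranks a
random negative (ties get half credit); AUPR is average precision with tied
scores processed as one threshold group.  Both are computed micro-style over
all test cells of a fold, then averaged over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from dhrls.kernels import KernelMatrix, gip_kernel
from dhrls.mkl import KernelBundle, combine, ideal_kernel, mean_combine, solve_weights
from dhrls.netio import AssociationMatrix
from dhrls.solver import SolverParams, fit, predict


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation configuration: mode CV1 (pair) or CV2 (disease)."""

    mode: str = "CV1"
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("CV1", "CV2"):
            raise ValueError(f"mode must be 'CV1' or 'CV2', got {self.mode!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


@dataclass
class CvFold:
    """One fold: masked training matrix plus boolean test-cell mask."""

    train: np.ndarray
    test_mask: np.ndarray


@dataclass
class CvReport:
    """Per-fold and aggregate AUC/AUPR."""

    per_fold: list[tuple[float, float]]
    params: dict = field(default_factory=dict)
    fold_weights_d: list[list[float]] = field(default_factory=list)
    fold_weights_g: list[list[float]] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([a for a, _ in self.per_fold]))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean([p for _, p in self.per_fold]))


def make_folds(Y: AssociationMatrix, scheme: CvScheme) -> list[CvFold]:
    """Split ``Y`` into train/test folds per the scheme.

    CV1 partitions the 1-entries; each fold's test cells are its held-out
    positives plus every 0-cell (ranking negatives).  CV2 partitions the
    rows; test cells are all cells of the held-out rows and those rows are
    zeroed in training.  A CV2 partition leaving some fold without a single
    positive is re-drawn with a shifted seed.
    """
    Yv = Y.values
    if Yv.size == 0:
        raise ValueError("empty association matrix")
    rng = np.random.default_rng(scheme.seed)

    if scheme.mode == "CV1":
        pos = np.argwhere(Yv == 1)
        if len(pos) < scheme.n_folds:
            raise ValueError("fewer positives than folds")
        order = rng.permutation(len(pos))
        groups = np.array_split(order, scheme.n_folds)
        zeros = Yv == 0
        folds = []
        for grp in groups:
            test_mask = zeros.copy()
            train = Yv.copy()
            for idx in grp:
                i, j = pos[idx]
                test_mask[i, j] = True
                train[i, j] = 0.0
            folds.append(CvFold(train=train, test_mask=test_mask))
        return folds

    n = Yv.shape[0]
    if scheme.n_folds > n:
        raise ValueError("CV2 requires n_folds <= number of diseases")
    for attempt in range(100):
        order = np.random.default_rng(scheme.seed + attempt).permutation(n)
        groups = np.array_split(order, scheme.n_folds)
        if all(Yv[grp].sum() > 0 for grp in groups):
            break
    else:
        raise ValueError("could not draw a CV2 partition with positives in every fold")
    folds = []
    for grp in groups:
        train = Yv.copy()
        train[grp] = 0.0
        test_mask = np.zeros_like(Yv, dtype=bool)
        test_mask[grp] = True
        folds.append(CvFold(train=train, test_mask=test_mask))
    return folds


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision (step-function area under the PR curve)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def _fold_bundle(
    Y_train: AssociationMatrix,
    side: str,
    side_kernels: Sequence[KernelMatrix],
    include_gip: bool,
    gamma: float,
) -> KernelBundle:
    kernels = list(side_kernels)
    if include_gip:
        kernels.append(gip_kernel(Y_train, side=side, gamma=gamma))
    return KernelBundle(kernels=kernels)


def _combined_kernel(
    bundle: KernelBundle, Y_train: AssociationMatrix, side: str, mkl_mode: str
) -> KernelMatrix:
    if mkl_mode == "cka":
        if len(bundle) == 1:
            bundle.weights = np.ones(1)
            return combine(bundle)
        solve_weights(bundle, ideal_kernel(Y_train, side=side))
        return combine(bundle)
    if mkl_mode == "mean":
        return mean_combine(bundle)
    if mkl_mode.startswith("single:"):
        name = mkl_mode.split(":", 1)[1]
        names = bundle.names
        if name not in names:
            raise ValueError(f"no kernel named {name!r}; have {names}")
        w = np.zeros(len(bundle))
        w[names.index(name)] = 1.0
        bundle.weights = w
        return combine(bundle)
    raise ValueError(f"unknown MKL mode {mkl_mode!r}")


def run_cv(
    Y: AssociationMatrix,
    scheme: CvScheme,
    params: SolverParams | None = None,
    disease_kernels: Sequence[KernelMatrix] = (),
    gene_kernels: Sequence[KernelMatrix] = (),
    mkl_mode: str = "cka",
    include_gip: bool = True,
    gamma: float = 0.5,
) -> CvReport:
    """Full cross-validated evaluation of the pipeline.

    Per fold: mask the training matrix, rebuild GIP and ideal kernels from
    it, fuse kernels per ``mkl_mode`` ("cka", "mean", or "single:<name>"),
    build the side Laplacians, fit, and score the fold's test cells.
    """
    params = params or SolverParams()
    folds = make_folds(Y, scheme)
    report = CvReport(per_fold=[], params={"scheme": vars(scheme) | {}, **vars(params)})
    for fold in folds:
        Y_train = AssociationMatrix(fold.train, list(Y.row_ids), list(Y.col_ids))
        bundle_d = _fold_bundle(Y_train, "disease", disease_kernels, include_gip, gamma)
        bundle_g = _fold_bundle(Y_train, "gene", gene_kernels, include_gip, gamma)
        Kd = _combined_kernel(bundle_d, Y_train, "disease", mkl_mode)
        Kg = _combined_kernel(bundle_g, Y_train, "gene", mkl_mode)
        report.fold_weights_d.append([float(x) for x in bundle_d.weights])
        report.fold_weights_g.append([float(x) for x in bundle_g.weights])
        model = fit(Y_train, Kd, Kg, params)
        F = predict(model)
        scores = F[fold.test_mask]
        labels = Y.values[fold.test_mask].astype(int)
        report.per_fold.append((auc(scores, labels), aupr(scores, labels)))
    return report


def default_grid() -> dict[str, list]:
    """The benchmark's hyperparameter grid: k in 10..100 step 10 and
    lambda_d, lambda_g in {2^-5, ..., 2^5}; beta fixed at 1."""
    lambdas = [2.0**e for e in range(-5, 6)]
    return {
        "knn_k": list(range(10, 101, 10)),
        "lambda_d": lambdas,
        "lambda_g": lambdas,
    }


def grid_search(
    Y: AssociationMatrix,
    grid: dict[str, list] | None = None,
    scheme: CvScheme | None = None,
    params: SolverParams | None = None,
    **cv_kwargs,
) -> tuple[SolverParams, CvReport, pd.DataFrame]:
    """Exhaustive hyperparameter search selecting by mean AUPR.

    Returns the best parameter set, its report, and the full grid table.
    """
    grid = grid if grid is not None else default_grid()
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty grid")
    scheme = scheme or CvScheme()
    base = params or SolverParams()
    rows = []
    best: tuple[SolverParams, CvReport] | None = None
    keys = list(grid)
    for values in product(*(grid[k] for k in keys)):
        p = replace(base, **dict(zip(keys, values)))
        report = run_cv(Y, scheme, p, **cv_kwargs)
        rows.append(
            dict(zip(keys, values))
            | {"mean_auc": report.mean_auc, "mean_aupr": report.mean_aupr}
        )
        if best is None or report.mean_aupr > best[1].mean_aupr:
            best = (p, report)
    table = pd.DataFrame(rows)
    assert best is not None
    return best[0], best[1], table
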