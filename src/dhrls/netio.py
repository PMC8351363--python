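"""I/O for bipartite association matrices, kernels, and predictions.

All formats are plain text: edge lists or dense tables for the association
matrix, dense tables with identifier headers for kernels, and a three-column
long table for ranked predictions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class AssociationMatrix:
    """Binary bipartite adjacency matrix Y with row/column identifiers.

    ``values[i, j] == 1`` iff the i-th row entity (disease) is associated
    with the j-th column entity (gene).
    """

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        if not self.row_ids:
            self.row_ids = [f"d{i}" for i in range(self.values.shape[0])]
        if not self.col_ids:
            self.col_ids = [f"g{j}" for j in range(self.values.shape[1])]
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length does not match matrix shape")
        if len(self.col_ids) != self.values.shape[1]:
            raise ValueError("col_ids length does not match matrix shape")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row identifiers")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column identifiers")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def n_edges(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive statistics of a bipartite network.

    link_density = |E| / (|V|·|W|); avg_degree = |E| / (|V|+|W|);
    left/right average degree = |E| / |V| and |E| / |W|.
    """

    n_left: int
    n_right: int
    n_edges: int
    link_density: float
    avg_degree: float
    left_avg_degree: float
    right_avg_degree: float


def network_stats_from_counts(n_left: int, n_right: int, n_edges: int) -> NetworkStats:
    """Statistics from the node/edge counts alone."""
    if n_left < 1 or n_right < 1:
        raise ValueError("both sides must be non-empty")
    return NetworkStats(
        n_left=n_left,
        n_right=n_right,
        n_edges=n_edges,
        link_density=n_edges / (n_left * n_right),
        avg_degree=n_edges / (n_left + n_right),
        left_avg_degree=n_edges / n_left,
        right_avg_degree=n_edges / n_right,
    )


def network_stats(Y: AssociationMatrix) -> NetworkStats:
    """Link density and average degrees of the bipartite network ``Y``."""
    if Y.n == 0 or Y.m == 0:
        raise ValueError("empty association matrix")
    return network_stats_from_counts(Y.n, Y.m, Y.n_edges)


def _detect_sep(text: str) -> str:
    for line in text.splitlines():
        if line.strip() and not line.startswith("#"):
            return "\t" if "\t" in line else ","
    raise ValueError("empty input")


def read_associations(source, dialect: str = "auto") -> AssociationMatrix:
    """Read an association matrix from an edge list or a dense table.

    Parameters
    ----------
    source
        Path or file-like object. Edge lists have two id columns and an
        optional third 0/1 column; dense tables have a header row and a
        leading id column. Tab- or comma-separated, auto-detected; lines
        starting with '#' are ignored.
    dialect
        ``"edgelist"``, ``"dense"``, or ``"auto"`` (dense iff the first
        non-comment row has more than three fields or a numeric body).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    if dialect not in ("auto", "edgelist", "dense"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    sep = _detect_sep(text)
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError("empty input")

    if dialect == "auto":
        n_fields = len(lines[0].split(sep))
        dialect = "edgelist" if n_fields <= 3 else "dense"

    if dialect == "edgelist":
        rows: list[str] = []
        cols: list[str] = []
        edges: set[tuple[str, str]] = set()
        seen_r: set[str] = set()
        seen_c: set[str] = set()
        for ln in lines:
            parts = [p.strip() for p in ln.split(sep)]
            if len(parts) not in (2, 3):
                raise ValueError(f"malformed edge-list line: {ln!r}")
            r, c = parts[0], parts[1]
            flag = 1.0 if len(parts) == 2 else float(parts[2])
            if flag not in (0.0, 1.0):
                raise ValueError(f"non-binary edge flag: {parts[2]!r}")
            if r not in seen_r:
                seen_r.add(r)
                rows.append(r)
            if c not in seen_c:
                seen_c.add(c)
                cols.append(c)
            if flag == 1.0:
                edges.add((r, c))
        values = np.zeros((len(rows), len(cols)))
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: j for j, c in enumerate(cols)}
        for r, c in edges:
            values[ri[r], ci[c]] = 1.0
        return AssociationMatrix(values, rows, cols)

    df = pd.read_csv(io.StringIO("\n".join(lines)), sep=sep, index_col=0)
    values = df.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("dense table contains non-binary values")
    return AssociationMatrix(values, [str(r) for r in df.index], [str(c) for c in df.columns])


def write_associations(Y: AssociationMatrix, sink) -> None:
    """Write ``Y`` as a dense tab-separated table with id headers."""
    df = pd.DataFrame(Y.values.astype(int), index=Y.row_ids, columns=Y.col_ids)
    df.to_csv(sink, sep="\t")


def write_predictions(
    F: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    sink,
) -> pd.DataFrame:
    """Write a score matrix as a long (row_id, col_id, score) table.

    Rows are sorted by score descending; ties broken lexicographically by
    (row_id, col_id) so output is deterministic.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (len(row_ids), len(col_ids)):
        raise ValueError("score matrix shape does not match identifier lists")
    df = pd.DataFrame(
        [
            (row_ids[i], col_ids[j], F[i, j])
            for i in range(F.shape[0])
            for j in range(F.shape[1])
        ],
        columns=["disease_id", "gene_id", "score"],
    )
    df = df.sort_values(
        ["score", "disease_id", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if sink is not None:
        df.to_csv(sink, sep="\t", index=False)
    return df


def read_kernel(source, name: str = "", side: str = "disease"):
    """Read a dense square similarity matrix with id headers as a KernelMatrix."""
    from dhrls.kernels import KernelMatrix

    df = pd.read_csv(source, sep=None, engine="python", index_col=0, comment="#")
    return KernelMatrix(
        values=df.to_numpy(dtype=float),
        entity_ids=[str(x) for x in df.index],
        name=name or "kernel",
        side=side,
    )


def write_kernel(K, sink) -> None:
    """Write a KernelMatrix as a dense tab-separated table with id headers."""
    df = pd.DataFrame(K.values, index=K.entity_ids, columns=K.entity_ids)
    df.to_csv(sink, sep="\t")
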