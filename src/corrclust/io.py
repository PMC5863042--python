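"""Delimited-text input/output.

Matrices and time series are plain comma-delimited text: '.' decimal, no
locale dependence, one optional header row of node labels. Square matrices
are written in full (not triangular) and symmetry is validated on read.
Floats are written with 17 significant digits so a write/read round trip is
exact to double precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .corr import validate_correlation_matrix, validate_timeseries
from .exceptions import MatrixValidationError

FLOAT_FORMAT = "%.17g"


def _read_delimited(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a CSV, auto-detecting an optional header row of labels."""
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = first.dtypes.apply(lambda d: d == object).any()
    df = pd.read_csv(path, header=0 if has_header else None)
    labels = [str(c) for c in df.columns] if has_header else None
    data = df.to_numpy(dtype=float)
    return data, labels


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """T x N time-series matrix (rows = time points) plus node labels if present."""
    data, labels = _read_delimited(path)
    return validate_timeseries(data), labels


def read_matrix(
    path: str | Path,
    *,
    sym_tol: float = 1e-8,
    check_psd: bool = True,
) -> tuple[np.ndarray, list[str] | None]:
    """Square correlation matrix plus node labels if present.

    Symmetry violations above ``sym_tol`` are an error naming the worst entry.
    """
    data, labels = _read_delimited(path)
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        raise MatrixValidationError(
            f"{path}: expected a square matrix, got shape {data.shape}"
        )
    return validate_correlation_matrix(data, sym_tol=sym_tol, check_psd=check_psd), labels


def read_square(
    path: str | Path,
    *,
    sym_tol: float = 1e-8,
) -> tuple[np.ndarray, list[str] | None]:
    """Square symmetric matrix (e.g. a covariance) without correlation-specific
    validation: no unit-diagonal or [-1, 1] requirement."""
    data, labels = _read_delimited(path)
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        raise MatrixValidationError(
            f"{path}: expected a square matrix, got shape {data.shape}"
        )
    asym = np.abs(data - data.T)
    if asym.size and asym.max() > sym_tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise MatrixValidationError(
            f"{path}: matrix not symmetric at entry ({i},{j}): "
            f"difference {asym[i, j]:.3g}"
        )
    return (data + data.T) / 2.0, labels


def write_matrix(path: str | Path, mat: np.ndarray, labels=None) -> None:
    mat = np.asarray(mat, dtype=float)
    df = pd.DataFrame(mat, columns=labels if labels is not None else None)
    df.to_csv(path, index=False, header=labels is not None, float_format=FLOAT_FORMAT)


def write_timeseries(path: str | Path, data: np.ndarray, labels=None) -> None:
    write_matrix(path, data, labels)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def network_edge_list(weights: np.ndarray, labels=None) -> pd.DataFrame:
    """Upper-triangular nonzero edges as (node_i, node_j, weight) rows."""
    n = weights.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    ii, jj = np.nonzero(np.triu(weights, k=1))
    return pd.DataFrame(
        {
            "node_i": [labels[i] for i in ii],
            "node_j": [labels[j] for j in jj],
            "weight": weights[ii, jj],
        }
    )
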