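"""Correlation estimation and triadic association measures.

This module houses the pairwise and three-way association measures that every
clustering coefficient builds on:

* sample Pearson correlation of a multivariate time series,
* the full partial correlation matrix (conditioning on all remaining nodes,
  via the inverse covariance),
* the three-way partial correlation rho_partial(j, l | i), conditioning on a
  single third node,
* the Gaussian partial (conditional) mutual information I(X_j, X_l | X_i),
  the closed form that the trivariate Gaussian entropy yields.

Conventions: matrices are plain ``numpy.ndarray``; a correlation matrix is
square, symmetric, with unit diagonal and entries in [-1, 1]. Validation is
explicit (``validate_correlation_matrix``) rather than wrapped in a class, so
arrays flow freely between modules.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import (
    DegenerateTripleError,
    IllConditionedError,
    MatrixValidationError,
    ZeroVarianceError,
)

#: default guard below which |rho| is treated as exactly 1 (degenerate triple)
DEGENERACY_EPS = 1e-12

#: relative eigenvalue threshold for the positive-semidefiniteness warning
PSD_WARN_FACTOR = 1e-8


def validate_timeseries(data: np.ndarray) -> np.ndarray:
    """Validate a T x N time-series matrix (rows = time points).

    Requires T >= 4 (the three-way partial correlation is degenerate below
    that) and no constant column.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise MatrixValidationError(f"time series must be 2-D, got shape {data.shape}")
    t, n = data.shape
    if t < 4:
        raise MatrixValidationError(f"need at least 4 time points, got {t}")
    sd = data.std(axis=0)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise ZeroVarianceError(
            f"column(s) {zero.tolist()} have zero variance; correlation undefined"
        )
    return data


def validate_correlation_matrix(
    rho: np.ndarray,
    *,
    sym_tol: float = 1e-8,
    check_psd: bool = True,
) -> np.ndarray:
    """Validate and canonicalise a correlation matrix.

    Checks squareness, symmetry (to ``sym_tol``), unit diagonal and the
    [-1, 1] range. Positive semi-definiteness is checked within a tolerance
    proportional to N; a violation beyond round-off scale triggers a warning,
    not a rejection, because delimited-text round-trips routinely perturb
    eigenvalues at that scale.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise MatrixValidationError(f"expected a square matrix, got shape {rho.shape}")
    n = rho.shape[0]
    asym = np.abs(rho - rho.T)
    if asym.size and asym.max() > sym_tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise MatrixValidationError(
            f"matrix not symmetric: |rho[{i},{j}] - rho[{j},{i}]| = {asym[i, j]:.3g}"
        )
    if np.abs(np.diag(rho) - 1.0).max() > sym_tol:
        i = int(np.argmax(np.abs(np.diag(rho) - 1.0)))
        raise MatrixValidationError(f"diagonal entry rho[{i},{i}] = {rho[i, i]!r} != 1")
    if np.abs(rho).max() > 1.0 + sym_tol:
        raise MatrixValidationError("correlation entries must lie in [-1, 1]")
    rho = (rho + rho.T) / 2.0
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    if check_psd:
        w_min = np.linalg.eigvalsh(rho)[0]
        if w_min < -PSD_WARN_FACTOR * n:
            warnings.warn(
                f"correlation matrix is not positive semi-definite "
                f"(smallest eigenvalue {w_min:.3g})",
                stacklevel=2,
            )
    return rho


def pearson_correlation(data: np.ndarray) -> np.ndarray:
    """Sample Pearson correlation matrix of a T x N time-series matrix.

    Columns are nodes. The diagonal is exactly 1 and the output satisfies all
    correlation-matrix invariants.
    """
    data = validate_timeseries(data)
    rho = np.corrcoef(data, rowvar=False)
    rho = np.atleast_2d(rho)
    np.clip(rho, -1.0, 1.0, out=rho)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return rho


def sample_covariance(data: np.ndarray, *, ddof: int = 0) -> np.ndarray:
    """Sample covariance of a T x N time-series matrix.

    ``ddof=0`` (denominator T) by default: the normalisation cancels in
    correlations, and the H-Q-S null model consumes these population-style
    moments.
    """
    data = validate_timeseries(data)
    return np.cov(data, rowvar=False, ddof=ddof)


def full_partial_correlation(
    corr_or_cov: np.ndarray,
    *,
    cond_max: float = 1e12,
) -> np.ndarray:
    """Partial correlation of every pair conditioning on all other N-2 nodes.

    Computed from the inverse covariance (precision) matrix P as
    ``-P[i,j] / sqrt(P[i,i] * P[j,j])``, with a unit diagonal by convention.
    Accepts either a correlation or a covariance matrix; the result is
    identical because the precision rescaling cancels row/column scalings.

    Raises ``IllConditionedError`` when the condition number exceeds
    ``cond_max``; regularised estimation is out of scope.
    """
    mat = np.asarray(corr_or_cov, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise MatrixValidationError(f"expected a square matrix, got shape {mat.shape}")
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > cond_max:
        raise IllConditionedError(
            f"matrix condition number {cond:.3g} exceeds {cond_max:.3g}; "
            "cannot form partial correlations (regularization is out of scope)"
        )
    prec = np.linalg.inv(mat)
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    pcorr = (pcorr + pcorr.T) / 2.0
    np.clip(pcorr, -1.0, 1.0, out=pcorr)
    np.fill_diagonal(pcorr, 1.0)
    return pcorr


def three_way_partial_correlation(
    rho_jl: float,
    rho_ij: float,
    rho_il: float,
    *,
    eps: float = DEGENERACY_EPS,
) -> float:
    """Partial correlation between nodes j and l controlling for node i only.

        rho_partial(j, l | i) =
            (rho(j,l) - rho(i,j) rho(i,l)) / sqrt((1 - rho(i,j)^2)(1 - rho(i,l)^2))

    The product rho(i,j)*rho(i,l) is the correlation expected from the
    indirect path j - i - l alone; the partial correlation measures the
    deviation from it.

    Raises ``DegenerateTripleError`` when |rho(i,j)| or |rho(i,l)| is within
    ``eps`` of 1 (node i is a perfect copy of a neighbour).
    """
    dj = 1.0 - rho_ij * rho_ij
    dl = 1.0 - rho_il * rho_il
    if dj <= eps or dl <= eps:
        raise DegenerateTripleError(
            f"|rho(i,j)|={abs(rho_ij):.6g} or |rho(i,l)|={abs(rho_il):.6g} is "
            "numerically 1; partial correlation undefined"
        )
    return (rho_jl - rho_ij * rho_il) / np.sqrt(dj * dl)


def gaussian_partial_mutual_information(
    rho_jl: float,
    rho_ij: float,
    rho_il: float,
    *,
    eps: float = DEGENERACY_EPS,
) -> float:
    """Partial mutual information I(X_j, X_l | X_i) for a Gaussian triple, in nats.

        I = 1/2 [ ln(1 - rho_ij^2) + ln(1 - rho_il^2) - ln det R3 ]

    where ``det R3 = 1 - rho_ij^2 - rho_il^2 - rho_jl^2 + 2 rho_ij rho_il rho_jl``
    is the determinant of the triple's correlation matrix. Equivalent to
    ``-1/2 ln(1 - rho_partial(j,l|i)^2)``; nonnegative, and zero exactly when
    the three-way partial correlation vanishes.

    Raises ``DegenerateTripleError`` when any log argument is within ``eps``
    of zero or below (a numerically singular triple).
    """
    dj = 1.0 - rho_ij * rho_ij
    dl = 1.0 - rho_il * rho_il
    det3 = 1.0 - rho_ij**2 - rho_il**2 - rho_jl**2 + 2.0 * rho_ij * rho_il * rho_jl
    if dj <= eps or dl <= eps or det3 <= eps:
        raise DegenerateTripleError(
            f"singular correlation triple (det={det3:.6g}); "
            "partial mutual information undefined"
        )
    return 0.5 * (np.log(dj) + np.log(dl) - np.log(det3))
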