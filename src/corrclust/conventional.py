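"""Conventional clustering coefficients used as comparators.

The unweighted coefficient operates on a binary network obtained by
thresholding the correlation matrix (either at a fixed correlation theta or
at a fixed edge density); the three weighted variants — Barrat, Onnela and
Zhang–Horvath — operate on the nonnegative weight matrix obtained by zeroing
negative correlations. The adjacency inside the weighted formulas is always
derived from weight positivity (a_ij = 1 iff w_ij > 0), not from any
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import LocalCoefficients
from .exceptions import MatrixValidationError


@dataclass
class UnweightedNetwork:
    """Binary symmetric adjacency matrix with zero diagonal."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise MatrixValidationError(f"adjacency must be square, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise MatrixValidationError("adjacency must be symmetric")
        if np.diag(a).any():
            raise MatrixValidationError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise MatrixValidationError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(float)

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class WeightedNetwork:
    """Nonnegative symmetric weight matrix with zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise MatrixValidationError(f"weights must be square, got {w.shape}")
        if not np.allclose(w, w.T, rtol=0.0, atol=0.0):
            raise MatrixValidationError("weights must be symmetric")
        if np.diag(w).any():
            raise MatrixValidationError("weight diagonal must be zero")
        if (w < 0).any():
            raise MatrixValidationError("weights must be nonnegative")
        self.weights = w

    @property
    def adjacency(self) -> np.ndarray:
        """Binary support: a_ij = 1 iff w_ij > 0."""
        return (self.weights > 0).astype(float)

    @property
    def strength(self) -> np.ndarray:
        """Node strength s_i = sum_j w_ij (weighted degree)."""
        return self.weights.sum(axis=1)

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def threshold_network(
    rho: np.ndarray,
    *,
    theta: float | None = None,
    edge_density: float | None = None,
) -> UnweightedNetwork:
    """Binarise a correlation matrix into an unweighted network.

    Exactly one rule must be given. With ``theta``, an edge is laid between i
    and j iff rho(i, j) >= theta. With ``edge_density`` d in (0, 1), exactly
    floor(d * N(N-1)/2) edges are kept, taking the largest off-diagonal
    correlations; ties at the cutoff are broken deterministically in
    lexicographic (i, j) order.
    """
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    if (theta is None) == (edge_density is None):
        raise ValueError("give exactly one of theta or edge_density")
    adj = np.zeros((n, n))
    if theta is not None:
        ii, jj = np.triu_indices(n, k=1)
        keep = rho[ii, jj] >= theta
        adj[ii[keep], jj[keep]] = 1.0
    else:
        if not 0.0 < edge_density < 1.0:
            raise ValueError(f"edge_density must be in (0, 1), got {edge_density}")
        m = int(np.floor(edge_density * n * (n - 1) / 2))
        ii, jj = np.triu_indices(n, k=1)
        vals = rho[ii, jj]
        # primary key: descending correlation; ties: ascending (i, j)
        order = np.lexsort((jj, ii, -vals))[:m]
        adj[ii[order], jj[order]] = 1.0
    adj = adj + adj.T
    return UnweightedNetwork(adj)


def positive_weight_network(rho: np.ndarray) -> WeightedNetwork:
    """Weighted network from a correlation matrix: w_ij = rho(i,j) if
    rho(i,j) > 0 else 0, with zero diagonal (negative edges are discarded,
    the common convention for functional connectivity)."""
    rho = np.asarray(rho, dtype=float)
    w = np.where(rho > 0, rho, 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w)


def local_clustering_unweighted(net: UnweightedNetwork) -> LocalCoefficients:
    """Watts–Strogatz local clustering: triangles at i over k_i(k_i-1)/2.

    Undefined at nodes with degree 0 or 1 (no potential triangle).
    """
    a = net.adjacency
    if a.shape[0] < 3:
        raise MatrixValidationError("need at least 3 nodes")
    k = net.degree
    triangles2 = np.einsum("ij,jk,ki->i", a, a, a)  # closed 3-walks = 2 * triangles at i
    defined = k >= 2
    denom = np.where(defined, k * (k - 1), 1.0)
    values = np.where(defined, triangles2 / denom, 0.0)
    return LocalCoefficients(values, defined, name="unw")


def local_clustering_barrat(net: WeightedNetwork) -> LocalCoefficients:
    """Barrat et al. weighted clustering.

        C_i = 1/(s_i (k_i - 1)) * sum_{j,l != i} (w_ij + w_il)/2 * a_ij a_il a_jl

    (ordered pair sum). Undefined when k_i <= 1 or s_i = 0. Reduces to the
    unweighted coefficient on binary weights.
    """
    w, a = net.weights, net.adjacency
    k, s = net.degree, net.strength
    # symmetrised ordered sum: sum_{j,l} w_ij a_ij a_il a_jl
    num = np.einsum("ij,il,jl->i", w, a, a)
    defined = (k >= 2) & (s > 0)
    denom = np.where(defined, s * (k - 1), 1.0)
    values = np.where(defined, num / denom, 0.0)
    return LocalCoefficients(values, defined, name="barrat")


def local_clustering_onnela(net: WeightedNetwork) -> LocalCoefficients:
    """Onnela et al. weighted clustering (geometric mean of triangle weights).

        C_i = 1/(k_i (k_i - 1)) * sum_{j,l != i} (w'_ij w'_il w'_jl)^(1/3)

    with w' = w / max(w). The max-normaliser keeps values in [0, 1] and makes
    the coefficient invariant under uniform rescaling of the weights; it is
    recomputed per matrix. On an all-zero network every node is undefined.
    """
    w = net.weights
    k = net.degree
    wmax = w.max()
    if wmax == 0.0:
        n = w.shape[0]
        return LocalCoefficients(np.zeros(n), np.zeros(n, dtype=bool), name="onnela")
    q = np.cbrt(w / wmax)
    num = np.einsum("ij,il,jl->i", q, q, q)
    defined = k >= 2
    denom = np.where(defined, k * (k - 1), 1.0)
    values = np.where(defined, num / denom, 0.0)
    return LocalCoefficients(values, defined, name="onnela")


def local_clustering_zhang(net: WeightedNetwork) -> LocalCoefficients:
    """Zhang–Horvath weighted clustering.

        C_i = sum_{j,l != i} w_ij w_il w_jl
              / [ max(w) * sum_{j != l, j,l != i} w_ij w_il ]

    Undefined when the denominator sum is zero (fewer than two positively
    weighted neighbours). Scale-invariant; reduces to the unweighted
    coefficient on binary weights.
    """
    w = net.weights
    wmax = w.max()
    if wmax == 0.0:
        n = w.shape[0]
        return LocalCoefficients(np.zeros(n), np.zeros(n, dtype=bool), name="zhang")
    num = np.einsum("ij,il,jl->i", w, w, w)
    s = net.strength
    den = s * s - (w * w).sum(axis=1)
    defined = den > 0
    denom = np.where(defined, wmax * den, 1.0)
    values = np.where(defined, num / denom, 0.0)
    return LocalCoefficients(values, defined, name="zhang")
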