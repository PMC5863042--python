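"""Clustering coefficients tailored to correlation matrices.

Conventional clustering coefficients applied to a correlation matrix are
confounded by indirect paths: if node i correlates strongly with both j and
l, then j and l correlate by roughly rho(i,j)*rho(i,l) even with no direct
association, which inflates triangle-based measures and couples them to node
strength. The coefficients here discount that effect by scoring each
triangle at node i by how much the j-l association *exceeds* the indirect
path through i:

* ``local_clustering_corr_A`` — a weighted average over pairs (j, l) of the
  absolute three-way partial correlation |rho_partial(j, l | i)|, with
  weights |rho(i,j) rho(i,l)|.
* ``local_clustering_corr_M`` — the same weighted average of the Gaussian
  partial mutual information I(X_j, X_l | X_i), normalised by
  (1 + ln 2*pi)/2 so that values nominally lie in [0, 1].

Both accept a sign filter restricting the sums to positive triangles (all
three pairwise correlations > 0) or negative triangles (all three < 0).
"""

from __future__ import annotations

import enum
import warnings

import numpy as np

from .containers import LocalCoefficients, global_clustering  # noqa: F401
from .corr import DEGENERACY_EPS
from .exceptions import DegenerateTripleError, MatrixValidationError

#: normaliser of the mutual-information coefficient: (1 + ln 2*pi)/2, the
#: differential entropy of a standard normal in nats
MI_NORMALIZER = 0.5 * (1.0 + np.log(2.0 * np.pi))


class TriangleSignFilter(str, enum.Enum):
    """Restriction of the triangle sums by the signs of the three correlations.

    ``positive`` keeps only triples with rho(i,j), rho(i,l), rho(j,l) all
    strictly > 0; ``negative`` only triples with all three strictly < 0;
    ``all`` imposes no restriction. Zero correlations belong to neither
    restricted variant.
    """

    ALL = "all"
    POSITIVE = "positive"
    NEGATIVE = "negative"


def _node_triple_arrays(rho: np.ndarray, i: int):
    """Correlations around node i: vector r to the others and their mutual block."""
    idx = np.arange(rho.shape[0]) != i
    r = rho[i, idx]
    block = rho[np.ix_(idx, idx)]
    return r, block


def _pair_mask(r: np.ndarray, block: np.ndarray, sign_filter: TriangleSignFilter):
    m = r.size
    upper = np.triu(np.ones((m, m), dtype=bool), k=1)
    if sign_filter is TriangleSignFilter.POSITIVE:
        upper &= (r[:, None] > 0) & (r[None, :] > 0) & (block > 0)
    elif sign_filter is TriangleSignFilter.NEGATIVE:
        upper &= (r[:, None] < 0) & (r[None, :] < 0) & (block < 0)
    return upper


def _check_degenerate(i: int, mask: np.ndarray, weights: np.ndarray,
                      degenerate: np.ndarray, what: str) -> None:
    bad = mask & degenerate & (weights > 0)
    if bad.any():
        j, l = np.argwhere(bad)[0]
        raise DegenerateTripleError(
            f"{what} undefined for a triple at node {i} "
            f"(neighbour pair offsets {int(j)}, {int(l)}): conditioning node is a "
            "numerically perfect copy of a neighbour"
        )


def local_clustering_corr_A(
    rho: np.ndarray,
    sign_filter: TriangleSignFilter | str = TriangleSignFilter.ALL,
    *,
    eps: float = DEGENERACY_EPS,
) -> LocalCoefficients:
    """Partial-correlation-based local clustering coefficient.

    For each node i,

        C_i = sum_{j<l, j,l!=i} |rho(i,j) rho(i,l) rho_partial(j,l|i)|
              / sum_{j<l, j,l!=i} |rho(i,j) rho(i,l)|

    restricted to the triples admitted by ``sign_filter``. A node with zero
    denominator (no admissible triple with nonzero weight) is undefined.
    Defined values lie in [0, 1].
    """
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    if n < 3:
        raise MatrixValidationError(f"need at least 3 nodes, got {n}")
    sign_filter = TriangleSignFilter(sign_filter)

    values = np.zeros(n)
    defined = np.zeros(n, dtype=bool)
    for i in range(n):
        r, block = _node_triple_arrays(rho, i)
        mask = _pair_mask(r, block, sign_filter)
        w = np.abs(np.outer(r, r))
        marg = 1.0 - r * r
        deg_pair = (marg[:, None] <= eps) | (marg[None, :] <= eps)
        _check_degenerate(i, mask, w, deg_pair, "partial correlation")
        safe = np.where(marg <= eps, 1.0, marg)
        partial = (block - np.outer(r, r)) / np.sqrt(np.outer(safe, safe))
        num = float((w * np.abs(partial))[mask & ~deg_pair].sum())
        den = float(w[mask].sum())
        if den > 0.0:
            values[i] = num / den
            defined[i] = True
    suffix = {"all": "", "positive": "+", "negative": "-"}[sign_filter.value]
    return LocalCoefficients(values, defined, name=f"cor_A{suffix}")


def local_clustering_corr_M(
    rho: np.ndarray,
    sign_filter: TriangleSignFilter | str = TriangleSignFilter.ALL,
    *,
    eps: float = DEGENERACY_EPS,
) -> LocalCoefficients:
    """Partial-mutual-information-based local clustering coefficient.

    For each node i,

        C_i = sum_{j<l} |rho(i,j) rho(i,l)| I(X_j, X_l | X_i)
              / [ (1 + ln 2*pi)/2 * sum_{j<l} |rho(i,j) rho(i,l)| ]

    with the Gaussian closed form of the partial mutual information, in nats.
    The normaliser is the nominal [0, 1] scaling; because I exceeds
    (1 + ln 2*pi)/2 once |rho_partial| > ~0.97, values can exceed 1 on
    near-singular matrices — they are reported as computed, with a warning,
    never clipped.
    """
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    if n < 3:
        raise MatrixValidationError(f"need at least 3 nodes, got {n}")
    sign_filter = TriangleSignFilter(sign_filter)

    values = np.zeros(n)
    defined = np.zeros(n, dtype=bool)
    for i in range(n):
        r, block = _node_triple_arrays(rho, i)
        mask = _pair_mask(r, block, sign_filter)
        w = np.abs(np.outer(r, r))
        marg = 1.0 - r * r
        det3 = (
            1.0
            - (r * r)[:, None]
            - (r * r)[None, :]
            - block * block
            + 2.0 * np.outer(r, r) * block
        )
        deg_pair = (marg[:, None] <= eps) | (marg[None, :] <= eps) | (det3 <= eps)
        _check_degenerate(i, mask, w, deg_pair, "partial mutual information")
        safe_marg = np.where(marg <= eps, 1.0, marg)
        safe_det = np.where(det3 <= eps, 1.0, det3)
        mi = 0.5 * (
            np.log(safe_marg)[:, None] + np.log(safe_marg)[None, :] - np.log(safe_det)
        )
        num = float((w * mi)[mask & ~deg_pair].sum())
        den = MI_NORMALIZER * float(w[mask].sum())
        if den > 0.0:
            values[i] = num / den
            defined[i] = True
    if (values[defined] > 1.0).any():
        warnings.warn(
            "a local mutual-information clustering value exceeds 1 "
            "(near-singular correlation triple); reported unclipped",
            stacklevel=2,
        )
    suffix = {"all": "", "positive": "+", "negative": "-"}[sign_filter.value]
    return LocalCoefficients(values, defined, name=f"cor_M{suffix}")
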