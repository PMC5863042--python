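"""Scalar and nodal connectivity summaries of a correlation matrix.

``s`` is the mean correlation over all node pairs and ``s_plus`` the same
mean restricted to pairs with nonnegative correlation. Per node, ``s_i`` is
the strength (sum of correlations to all other nodes), ``s_i_plus`` the sum
over strictly positive correlations only, and ``s_tilde`` the strength
normalised by N - 1 so it lies in [-1, 1].

Note the deliberate asymmetry of conventions, kept as defined: the scalar
``s_plus`` averages over pairs with rho >= 0 (nonnegative), while the nodal
``s_i_plus`` sums over rho > 0 (strictly positive). Zero correlations are
measure-zero in practice, so the distinction rarely matters numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import MatrixValidationError


@dataclass
class ConnectivitySummary:
    s: float
    s_plus: float | None      # None when no pair has rho >= 0
    s_i: np.ndarray
    s_i_plus: np.ndarray
    s_tilde: np.ndarray

    def nodal_frame(self, labels=None) -> pd.DataFrame:
        n = self.s_i.size
        if labels is None:
            labels = [str(i) for i in range(n)]
        return pd.DataFrame(
            {
                "node": list(labels),
                "strength": self.s_i,
                "strength_positive": self.s_i_plus,
                "strength_normalized": self.s_tilde,
            }
        )


def connectivity_summary(rho: np.ndarray) -> ConnectivitySummary:
    """Compute all connectivity summaries; the diagonal is excluded throughout."""
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1] or n < 2:
        raise MatrixValidationError(f"expected a square matrix with N >= 2, got {rho.shape}")
    off_mask = ~np.eye(n, dtype=bool)
    off = rho[off_mask]
    s = float(off.mean())
    nonneg = off[off >= 0]
    s_plus = float(nonneg.mean()) if nonneg.size else None
    s_i = np.where(off_mask, rho, 0.0).sum(axis=1)
    s_i_plus = np.where(off_mask & (rho > 0), rho, 0.0).sum(axis=1)
    return ConnectivitySummary(
        s=s,
        s_plus=s_plus,
        s_i=s_i,
        s_i_plus=s_i_plus,
        s_tilde=s_i / (n - 1),
    )
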