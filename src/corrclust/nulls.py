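"""Null-model generators for correlation matrices.

Two nulls are provided:

* ``white_noise_correlation`` — the sample correlation matrix of N
  independent standard-normal series of length T. Even with no true
  association, finite T produces nonzero sample correlations (off-diagonal
  sd ~ 1/sqrt(T-1)), which sets the chance level of every coefficient.

* the Hirschberger–Qu–Steuer (H-Q-S) algorithm — a random covariance
  matrix built as the Gram matrix of short latent white-noise samples with a
  positive bias, matched to three moments of a reference covariance: the
  mean of the diagonal elements (mu_on), and the mean and variance of the
  off-diagonal elements (mu_off, sigma2_off). Being a Gram matrix, the
  output is positive semi-definite by construction; it is then normalised to
  a correlation matrix. This nulls the correlation structure while keeping
  the gross level and spread of connectivity, which topology-randomising
  nulls do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import HQSPreconditionError, MatrixValidationError


@dataclass(frozen=True)
class HQSMoments:
    """The three moments of a reference covariance that H-Q-S preserves."""

    mu_on: float      # mean of the diagonal elements
    mu_off: float     # mean of the strict off-diagonal elements
    sigma2_off: float  # population variance of the off-diagonal elements
    n: int            # matrix size

    def __post_init__(self) -> None:
        if self.mu_off <= 0:
            raise HQSPreconditionError(
                f"mean off-diagonal covariance mu_off = {self.mu_off:.6g} <= 0; "
                "the H-Q-S algorithm requires a positive mean off-diagonal element"
            )
        if self.sigma2_off <= 0:
            raise HQSPreconditionError(
                f"off-diagonal variance sigma2_off = {self.sigma2_off:.6g} <= 0; "
                "degenerate reference covariance"
            )
        if self.mu_on <= 0:
            raise HQSPreconditionError(f"mu_on = {self.mu_on:.6g} <= 0")

    @property
    def t_bar_max(self) -> int:
        """Latent sample length: max(2, floor((mu_on^2 - mu_off^2) / sigma2_off))."""
        return max(2, int(np.floor((self.mu_on**2 - self.mu_off**2) / self.sigma2_off)))

    def latent_normal_params(self, *, literal_parameterization: bool = False):
        """Mean and variance of the latent normal variates x_{i,t}.

        The standard parameterization is mean sqrt(mu_off / t_bar) and
        variance -mu_off/t_bar + sqrt(mu_off^2/t_bar^2 + sigma2_off/t_bar);
        it is the unique choice for which E[cov_ij] = mu_off,
        Var[cov_ij] = sigma2_off and E[cov_ii] = sqrt(mu_off^2 +
        t_bar * sigma2_off) ~= mu_on. The ``literal_parameterization``
        variant (mean mu_off/t_bar, variance -mu_off/t_bar + mu_off^2/t_bar^2
        + sigma2_off/t_bar) drops the radicals and preserves none of the
        moments; it exists only for auditing.
        """
        t_bar = self.t_bar_max
        if literal_parameterization:
            mean = self.mu_off / t_bar
            var = -self.mu_off / t_bar + self.mu_off**2 / t_bar**2 + self.sigma2_off / t_bar
        else:
            mean = np.sqrt(self.mu_off / t_bar)
            var = -self.mu_off / t_bar + np.sqrt(
                self.mu_off**2 / t_bar**2 + self.sigma2_off / t_bar
            )
        if var <= 0:
            raise HQSPreconditionError(
                f"latent variance {var:.6g} <= 0 under these moments"
            )
        return float(mean), float(var)


def hqs_moments(cov: np.ndarray) -> HQSMoments:
    """Extract the H-Q-S target moments from a reference covariance matrix.

    The off-diagonal variance is the population variance over the strict
    off-diagonal entries. Raises ``HQSPreconditionError`` when the mean
    off-diagonal element is not positive (the algorithm's precondition) or
    when the off-diagonal entries are all equal.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise MatrixValidationError(f"expected a square matrix, got {cov.shape}")
    if not np.allclose(cov, cov.T, rtol=0.0, atol=1e-8):
        raise MatrixValidationError("covariance matrix must be symmetric")
    n = cov.shape[0]
    if n < 2:
        raise MatrixValidationError("need at least a 2 x 2 covariance")
    off = cov[~np.eye(n, dtype=bool)]
    return HQSMoments(
        mu_on=float(np.diag(cov).mean()),
        mu_off=float(off.mean()),
        sigma2_off=float(off.var()),
        n=n,
    )


def hqs_covariance(
    moments: HQSMoments,
    seed: int | np.random.Generator,
    *,
    literal_parameterization: bool = False,
) -> np.ndarray:
    """One random covariance matrix from the H-Q-S construction.

    Draws N * t_bar_max iid normal variates x_{i,t} and forms
    cov_ij = sum_t x_{i,t} x_{j,t} — a Gram matrix, hence exactly PSD.
    """
    rng = np.random.default_rng(seed)
    mean, var = moments.latent_normal_params(
        literal_parameterization=literal_parameterization
    )
    x = rng.normal(mean, np.sqrt(var), size=(moments.n, moments.t_bar_max))
    return x @ x.T


def hqs_generate(
    moments: HQSMoments,
    seed: int | np.random.Generator,
    *,
    literal_parameterization: bool = False,
) -> np.ndarray:
    """One random correlation matrix: the H-Q-S covariance normalised to unit
    diagonal. One seed governs one matrix."""
    cov = hqs_covariance(
        moments, seed, literal_parameterization=literal_parameterization
    )
    d = np.sqrt(np.diag(cov))
    rho = cov / np.outer(d, d)
    rho = (rho + rho.T) / 2.0
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    return rho


def white_noise_correlation(
    n: int,
    t: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample correlation matrix of n independent standard-normal series of
    length t (white-noise null)."""
    if n < 3:
        raise ValueError(f"need at least 3 nodes, got {n}")
    if t < 4:
        raise ValueError(f"need at least 4 time points, got {t}")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal(size=(t, n))
    rho = np.corrcoef(data, rowvar=False)
    rho = (rho + rho.T) / 2.0
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    return rho
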