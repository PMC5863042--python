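import numpy as np
import pytest


def random_correlation(rng: np.random.Generator, n: int, t: int | None = None) -> np.ndarray:
    """Random sample correlation matrix (Gram-based, hence a valid PSD
    correlation matrix with probability one)."""
    if t is None:
        t = n + 10
    data = rng.standard_normal(size=(t, n))
    rho = np.corrcoef(data, rowvar=False)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return rho


def random_valid_triple(rng: np.random.Generator) -> tuple[float, float, float]:
    """(rho_jl, rho_ij, rho_il) from a random valid 3-node correlation matrix."""
    r = random_correlation(rng, 3, t=8)
    return r[1, 2], r[0, 1], r[0, 2]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
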