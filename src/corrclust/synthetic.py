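"""Structured synthetic time series with known population correlations.

These fixtures exist to separate the two mechanisms that make triangles:
shared drivers (indirect paths) and genuine mutual coupling. Each signal is
built from latent standard-normal factors as

    x = sqrt(coupling) * factor + sqrt(1 - coupling) * noise,

so every population correlation is known in closed form and every
downstream expectation is derivable analytically:

* ``common_driver`` — node 0 is a hub whose signal drives every other node
  independently. Population correlations: rho(hub, j) = sqrt(coupling) and
  rho(j, l) = coupling = rho(hub, j) * rho(hub, l) exactly, so every
  peripheral pair's correlation is purely the indirect path through the hub
  and the three-way partial correlation given the hub is exactly zero.
  Conventional weighted clustering at the hub stays large.

* ``direct_triad`` — a designated node triple shares a triad factor (mutual
  direct coupling); the remaining nodes are independent noise. Within the
  triad, rho = coupling and the partial correlation given the third member
  is coupling / (1 + coupling) > 0.

* ``block`` — disjoint groups each share a group factor; within-group
  rho = coupling, between-group rho = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRUCTURES = ("common_driver", "direct_triad", "block")


@dataclass(frozen=True)
class PlantedStructureSpec:
    """Recipe for a structured multivariate Gaussian series."""

    n: int
    t: int
    structure: str
    coupling: float
    seed: int
    triad: tuple[int, int, int] = field(default=(0, 1, 2))
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}, got {self.structure!r}")
        if not 0.0 < self.coupling < 1.0:
            raise ValueError(f"coupling must be in (0, 1), got {self.coupling}")
        if self.n < 3:
            raise ValueError("need at least 3 nodes")
        if self.t < 4:
            raise ValueError("need at least 4 time points")
        if self.structure == "direct_triad":
            if len(set(self.triad)) != 3 or not all(0 <= v < self.n for v in self.triad):
                raise ValueError(f"triad must be 3 distinct node indices < n, got {self.triad}")
        if self.structure == "block" and not 1 <= self.n_blocks <= self.n:
            raise ValueError("n_blocks must be between 1 and n")


def generate_structured_series(spec: PlantedStructureSpec) -> np.ndarray:
    """T x N Gaussian series realising ``spec``; reproducible under its seed."""
    rng = np.random.default_rng(spec.seed)
    c = spec.coupling
    a, b = np.sqrt(c), np.sqrt(1.0 - c)
    noise = rng.standard_normal(size=(spec.t, spec.n))

    if spec.structure == "common_driver":
        hub = rng.standard_normal(size=spec.t)
        x = a * hub[:, None] + b * noise
        x[:, 0] = hub
    elif spec.structure == "direct_triad":
        factor = rng.standard_normal(size=spec.t)
        x = noise.copy()
        for node in spec.triad:
            x[:, node] = a * factor + b * noise[:, node]
    else:  # block
        groups = np.array_split(np.arange(spec.n), spec.n_blocks)
        factors = rng.standard_normal(size=(spec.t, spec.n_blocks))
        x = noise.copy()
        for g, nodes in enumerate(groups):
            x[:, nodes] = a * factors[:, [g]] + b * noise[:, nodes]
    return x
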