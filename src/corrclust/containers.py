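"""Shared result containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import UndefinedGlobalError


@dataclass
class LocalCoefficients:
    """Per-node coefficient values with per-node defined/undefined flags.

    ``values[i]`` is meaningful only where ``defined[i]`` is True (an
    undefined node has no admissible triangle, or degree <= 1). The global
    coefficient is the arithmetic mean over *defined* nodes only — undefined
    nodes are excluded from, never zero-filled into, the average.
    """

    values: np.ndarray
    defined: np.ndarray
    name: str = field(default="")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != self.defined.shape or self.values.ndim != 1:
            raise ValueError("values and defined must be 1-D vectors of equal length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_undefined(self) -> int:
        return int((~self.defined).sum())

    def global_coefficient(self) -> float:
        """Mean over defined nodes; raises if no node is defined."""
        if not self.defined.any():
            raise UndefinedGlobalError(
                f"{self.name or 'coefficient'}: no node has a defined value; "
                "global coefficient undefined"
            )
        return float(self.values[self.defined].mean())

    def to_frame(self, labels=None) -> pd.DataFrame:
        """Long-format table: node label, coefficient name, value, defined flag."""
        n = len(self)
        if labels is None:
            labels = [str(i) for i in range(n)]
        vals = np.where(self.defined, self.values, np.nan)
        return pd.DataFrame(
            {
                "node": list(labels),
                "coefficient": self.name,
                "value": vals,
                "defined": self.defined,
            }
        )


def global_clustering(local: LocalCoefficients) -> float:
    """Global clustering coefficient: average of the local values over the
    nodes where they are defined."""
    return local.global_coefficient()
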