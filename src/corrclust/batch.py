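"""Batch runner: every selected coefficient for one or many inputs.

``run_batch`` reads each input (time series or precomputed correlation
matrix), computes the selected local and global coefficients plus the
connectivity summaries, and writes per-input nodal and global tables in
tidy long format, together with a run manifest (configuration, seeds,
package version) that makes the run reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    TriangleSignFilter,
    local_clustering_corr_A,
    local_clustering_corr_M,
)
from .connectivity import connectivity_summary
from .containers import LocalCoefficients
from .conventional import (
    local_clustering_barrat,
    local_clustering_onnela,
    local_clustering_unweighted,
    local_clustering_zhang,
    positive_weight_network,
    threshold_network,
)
from .corr import pearson_correlation
from .exceptions import CorrclustError
from .io import read_matrix, read_timeseries, write_table

logger = logging.getLogger("corrclust")

COEFFICIENTS = ("cor_A", "cor_M", "unw", "barrat", "onnela", "zhang")


@dataclass
class RunConfig:
    """Configuration of one batch run."""

    inputs: list[str]
    kind: str = "correlation"                  # "timeseries" | "correlation"
    coefficients: tuple[str, ...] = COEFFICIENTS
    sign_filters: tuple[str, ...] = ("all",)   # applies to cor_A / cor_M
    theta: float | None = None
    edge_density: float | None = None
    out_dir: str = "."
    continue_on_error: bool = False
    wide: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("timeseries", "correlation"):
            raise ValueError(f"kind must be 'timeseries' or 'correlation', got {self.kind!r}")
        unknown = set(self.coefficients) - set(COEFFICIENTS)
        if unknown:
            raise ValueError(f"unknown coefficient(s): {sorted(unknown)}")
        for f in self.sign_filters:
            TriangleSignFilter(f)
        if "unw" in self.coefficients and self.theta is None and self.edge_density is None:
            raise ValueError(
                "the unweighted coefficient needs a threshold rule "
                "(theta or edge_density)"
            )
        if self.theta is not None and self.edge_density is not None:
            raise ValueError("theta and edge_density are mutually exclusive")

    def to_dict(self) -> dict:
        return {
            "inputs": list(self.inputs),
            "kind": self.kind,
            "coefficients": list(self.coefficients),
            "sign_filters": list(self.sign_filters),
            "theta": self.theta,
            "edge_density": self.edge_density,
            "out_dir": str(self.out_dir),
            "continue_on_error": self.continue_on_error,
            "wide": self.wide,
        }


def compute_coefficients(
    rho: np.ndarray,
    config: RunConfig,
    labels=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nodal (long-format) and global tables for one correlation matrix."""
    locals_: list[LocalCoefficients] = []
    if "cor_A" in config.coefficients:
        for f in config.sign_filters:
            locals_.append(local_clustering_corr_A(rho, f))
    if "cor_M" in config.coefficients:
        for f in config.sign_filters:
            locals_.append(local_clustering_corr_M(rho, f))
    if "unw" in config.coefficients:
        net = threshold_network(rho, theta=config.theta, edge_density=config.edge_density)
        locals_.append(local_clustering_unweighted(net))
    wnet = None
    for name, fn in (
        ("barrat", local_clustering_barrat),
        ("onnela", local_clustering_onnela),
        ("zhang", local_clustering_zhang),
    ):
        if name in config.coefficients:
            if wnet is None:
                wnet = positive_weight_network(rho)
            locals_.append(fn(wnet))

    nodal = pd.concat([lc.to_frame(labels) for lc in locals_], ignore_index=True)

    conn = connectivity_summary(rho)
    strengths = conn.nodal_frame(labels).melt(
        id_vars="node", var_name="coefficient", value_name="value"
    )
    strengths["defined"] = True
    nodal = pd.concat([nodal, strengths], ignore_index=True)

    global_rows = []
    for lc in locals_:
        try:
            g = lc.global_coefficient()
        except CorrclustError:
            g = np.nan
        global_rows.append(
            {"coefficient": lc.name, "value": g, "n_undefined": lc.n_undefined}
        )
    global_rows.append({"coefficient": "s", "value": conn.s, "n_undefined": 0})
    global_rows.append(
        {
            "coefficient": "s_plus",
            "value": conn.s_plus if conn.s_plus is not None else np.nan,
            "n_undefined": 0,
        }
    )
    return nodal, pd.DataFrame(global_rows)


@dataclass
class BatchResult:
    n_ok: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        return 1 if self.failures else 0


def run_batch(config: RunConfig) -> BatchResult:
    """Run the batch; one nodal and one global table per input, plus a manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = BatchResult()
    for path in config.inputs:
        stem = Path(path).stem
        try:
            if config.kind == "timeseries":
                data, labels = read_timeseries(path)
                rho = pearson_correlation(data)
            else:
                rho, labels = read_matrix(path)
            nodal, glob = compute_coefficients(rho, config, labels)
            if config.wide:
                nodal_out = nodal.pivot(index="node", columns="coefficient", values="value").reset_index()
            else:
                nodal_out = nodal
            write_table(out_dir / f"{stem}_nodal.csv", nodal_out)
            write_table(out_dir / f"{stem}_global.csv", glob)
            result.n_ok += 1
        except (CorrclustError, OSError, ValueError) as exc:
            logger.error("input %s failed: %s", path, exc)
            result.failures.append((str(path), str(exc)))
            if not config.continue_on_error:
                raise
    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "n_ok": result.n_ok,
        "failures": result.failures,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
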