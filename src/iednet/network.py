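"""Weighted graph segregation and integration on unthresholded matrices.

Segregation is measured by the Onnela weighted clustering coefficient
(weights normalized by the matrix maximum, triangle intensity as the
geometric mean of its edge weights); its average over nodes is the
network-level segregation.  Integration is measured by nodal efficiency
(mean inverse weighted shortest-path length, with edge lengths 1/w);
global efficiency is the nodal mean.  Matrices are symmetric with
entries in [0, 1]; missing entries (uncovered ROI pairs, diagonal) are
treated as absent edges (weight 0).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

__all__ = ["NetworkMetrics", "clustering_coefficient", "efficiency",
           "network_metrics"]


@dataclasses.dataclass
class NetworkMetrics:
    labels: list[str]
    clustering: np.ndarray          # per node, in [0, 1]
    nodal_efficiency: np.ndarray    # per node, in [0, 1]
    mean_clustering: float          # network segregation
    global_efficiency: float        # network integration
    method: str = "onnela clustering; nodal efficiency with lengths 1/w"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"unit": self.labels,
                             "clustering": self.clustering,
                             "nodal_efficiency": self.nodal_efficiency})


def _clean(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, equal_nan=True):
        raise ValueError("W must be symmetric")
    W = np.where(np.isfinite(W), W, 0.0)   # missing entries -> no edge
    if W.min() < -1e-12 or W.max() > 1 + 1e-12:
        raise ValueError("weights must lie in [0, 1]")
    np.fill_diagonal(W, 0.0)
    return W


def clustering_coefficient(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node, plus the network mean.

    ``w_hat = W / max(W)``;
    ``C_i = [ (w_hat^{1/3})^3 ]_ii / (k_i (k_i - 1))`` with ``k_i`` the
    number of nonzero neighbours; ``C_i = 0`` when ``k_i < 2``.
    Invariant under multiplying all weights by a constant.
    """
    W = _clean(W)
    wmax = W.max()
    if wmax == 0:
        return np.zeros(W.shape[0]), 0.0
    cube_root = np.cbrt(W / wmax)
    triangles = np.diagonal(cube_root @ cube_root @ cube_root)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def efficiency(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal efficiency per node and global efficiency.

    Edge lengths are 1/w (infinite for absent edges); ``NE_i`` is the
    mean of ``1/d_ij`` over j != i; global efficiency is the mean NE.
    Scales linearly with a uniform weight factor.
    """
    W = _clean(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    d = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    ne = inv.sum(axis=1) / (n - 1)
    return ne, float(ne.mean())


def network_metrics(W: np.ndarray, labels: list[str] | None = None) -> NetworkMetrics:
    """Bundle clustering and efficiency for one connectivity matrix."""
    c, mc = clustering_coefficient(W)
    ne, ge = efficiency(W)
    if labels is None:
        labels = [f"n{i}" for i in range(len(c))]
    return NetworkMetrics(labels, c, ne, mc, ge)
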