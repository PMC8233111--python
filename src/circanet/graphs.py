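"""Weighted graph-theoretical summaries of a connectivity network.

Works on symmetric channel x channel matrices of connection fractions.
Degree is the sum of incident weights.  The clustering coefficient is the
weighted (geometric-mean) variant computed on the max-normalized network.
Path lengths use edge length = 1 / weight on the max-normalized network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra


def _check_network(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("network must be a square matrix")
    if not np.allclose(W, W.T):
        raise ValueError("network must be symmetric")
    return W


def weighted_degree(W: np.ndarray) -> np.ndarray:
    """Per-node degree: sum of the weights of incident connections."""
    W = _check_network(W)
    return W.sum(axis=1) - np.diag(W)


def normalize_by_max(W: np.ndarray) -> np.ndarray:
    """Divide every element by the maximum connection value."""
    W = _check_network(W)
    m = W.max()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero network")
    return W / m


def clustering_onnela(W: np.ndarray) -> np.ndarray:
    """Weighted clustering coefficient (geometric mean of triangle weights).

    C_i = sum_{j,h} (w_ij * w_ih * w_jh)^(1/3) / (k_i * (k_i - 1)), where
    k_i counts the neighbours with nonzero weight; C_i = 0 when k_i < 2.
    Expects a max-normalized network with entries in [0, 1].
    """
    W = _check_network(W)
    if np.any((W < 0) | (W > 1)):
        raise ValueError("normalized weights must lie in [0, 1]")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    cube = np.cbrt(W)
    num = np.diag(cube @ cube @ cube)  # 2 * sum over triangles at each node
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, num / denom, 0.0)
    return c


def shortest_paths(W: np.ndarray) -> tuple[np.ndarray, float]:
    """All-pairs shortest inverse-weight path lengths.

    Edge length is 1/weight for positive weights; zero-weight pairs have no
    direct edge.  Returns the distance matrix and the characteristic path
    length (mean over connected ordered node pairs); disconnected pairs are
    excluded from the mean with a warning.
    """
    W = _check_network(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    D = dijkstra(lengths, directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    if finite.sum() < off.sum():
        warnings.warn("disconnected node pairs excluded from the "
                      "characteristic path length")
    if finite.sum() == 0:
        return D, float("nan")
    return D, float(D[finite].mean())


@dataclass
class GraphMetrics:
    """Node-level metrics and their network-level means."""

    degree: np.ndarray
    clustering: np.ndarray
    path_matrix: np.ndarray
    char_path_length: float

    @property
    def mean_degree(self) -> float:
        return float(self.degree.mean())

    @property
    def mean_clustering(self) -> float:
        return float(self.clustering.mean())


def graph_metrics(W: np.ndarray) -> GraphMetrics:
    """Degree on the raw weights; clustering and paths on the
    max-normalized network."""
    deg = weighted_degree(W)
    Wn = normalize_by_max(W)
    clus = clustering_onnela(Wn)
    D, cpl = shortest_paths(Wn)
    return GraphMetrics(degree=deg, clustering=clus,
                        path_matrix=D, char_path_length=cpl)
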