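"""Weighted spatial k-nearest-neighbor graph over spatial cells.

Edges connect each cell to its k nearest Euclidean neighbors, weighted by
the Gaussian kernel W(u,v) = exp(-d(u,v)^2 / (2 theta^2)) so that closer
cells are more strongly connected. The decay coefficient theta defaults to
"auto" — the median k-NN distance — which makes the kernel scale-free
across platforms whose coordinates are in different units (pixels vs
micrometers). The adjacency is symmetrized by elementwise maximum, which
preserves the kernel value of every selected directed edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

DEFAULT_K_NEIGHBORS = 30


def gaussian_weight(d, theta: float):
    """Gaussian kernel weight exp(-d^2 / (2 theta^2)); 1 iff d == 0."""
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    out = np.exp(-(d**2) / (2.0 * theta**2))
    return float(out) if out.ndim == 0 else out


@dataclass
class SpatialGraph:
    """Symmetric weighted k-NN adjacency A plus its normalized form.

    ``adjacency`` has a zero diagonal (a cell is not its own neighbor);
    self-loops enter only in ``normalized``, the symmetrically normalized
    matrix used by the graph convolutions.
    """

    adjacency: sp.csr_matrix
    theta: float
    k_neighbors: int
    normalized: sp.csr_matrix | None = None

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def binarized(self) -> sp.csr_matrix:
        out = self.adjacency.copy()
        out.data = np.ones_like(out.data)
        return out


def build_graph(coords: np.ndarray, k_neighbors: int = DEFAULT_K_NEIGHBORS,
                theta: float | str = "auto") -> SpatialGraph:
    """Build the symmetrized Gaussian-weighted k-NN graph over coordinates.

    theta="auto" resolves to the median k-NN distance over all cells.
    Duplicate coordinates are allowed (zero-distance edges get weight 1);
    if k >= n-1 the graph saturates to the complete graph with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to build a graph")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates contain non-finite values")
    k = min(k_neighbors, n - 1)
    if k < k_neighbors:
        logger.warning("k_neighbors=%d >= n=%d: building the complete graph", k_neighbors, n)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    if theta == "auto":
        theta_val = float(np.median(dist))
        if theta_val <= 0:
            theta_val = 1.0  # all-duplicate degenerate case
    else:
        theta_val = float(theta)
        if theta_val <= 0:
            raise ValueError(f"theta must be positive, got {theta_val}")

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    weights = gaussian_weight(dist.ravel(), theta_val)
    directed = sp.csr_matrix((weights, (rows, cols)), shape=(n, n))
    adjacency = directed.maximum(directed.T).tocsr()
    adjacency.setdiag(0.0)
    adjacency.eliminate_zeros()
    return SpatialGraph(adjacency=adjacency, theta=theta_val, k_neighbors=k_neighbors)


def normalize_adjacency(g: SpatialGraph) -> SpatialGraph:
    """Store the symmetric normalization D^(-1/2) (A + I) D^(-1/2) on ``g``."""
    a_hat = g.adjacency + sp.identity(g.n_cells, format="csr")
    deg = np.asarray(a_hat.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    d_inv = sp.diags(inv_sqrt)
    g.normalized = (d_inv @ a_hat @ d_inv).tocsr()
    return g
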