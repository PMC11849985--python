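"""Signed shortest-path distance from domain boundaries over the lattice graph.

Every grid is a node; 8-adjacent grids are joined by edges of weight 1
(orthogonal) or sqrt(2) (diagonal) in pitch units.  The distance of a grid is
the length of the shortest path to the nearest boundary grid (multi-source
Dijkstra over the full lattice; domains are not obstacles), scaled to µm by
the pitch.  The sign is negative strictly inside a domain, zero on boundary
grids and positive outside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

__all__ = ["DistanceField", "lattice_graph", "compute_distance_field"]

_SQRT2 = np.sqrt(2.0)


@dataclass
class DistanceField:
    """Per-grid signed boundary distance in µm (``(n_rows, n_cols)`` array)."""

    values: np.ndarray
    pitch: float
    degenerate: bool = False


def lattice_graph(n_rows: int, n_cols: int) -> sp.csr_matrix:
    """Symmetric 8-adjacency graph of the lattice, weights in pitch units."""
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    src, dst, wgt = [], [], []

    def add(a: np.ndarray, b: np.ndarray, w: float) -> None:
        src.append(a.ravel())
        dst.append(b.ravel())
        wgt.append(np.full(a.size, w))

    add(idx[:, :-1], idx[:, 1:], 1.0)  # east
    add(idx[:-1, :], idx[1:, :], 1.0)  # south
    add(idx[:-1, :-1], idx[1:, 1:], _SQRT2)  # south-east
    add(idx[:-1, 1:], idx[1:, :-1], _SQRT2)  # south-west
    n = n_rows * n_cols
    graph = sp.coo_matrix(
        (np.concatenate(wgt), (np.concatenate(src), np.concatenate(dst))), shape=(n, n)
    )
    return (graph + graph.T).tocsr()


def compute_distance_field(
    mask: np.ndarray, boundary: np.ndarray, pitch: float
) -> DistanceField:
    """Signed multi-source shortest-path distance from the boundary set.

    ``boundary`` must be a subset of ``mask``.  With an empty mask the field
    is all +inf and flagged degenerate.
    """
    if mask.shape != boundary.shape:
        raise ValueError("mask and boundary shapes differ")
    if (boundary & ~mask).any():
        raise ValueError("boundary grids must lie inside the domain mask")
    if not mask.any():
        return DistanceField(
            values=np.full(mask.shape, np.inf), pitch=pitch, degenerate=True
        )
    if not boundary.any():
        raise ValueError("nonempty mask requires a nonempty boundary")

    n_rows, n_cols = mask.shape
    graph = lattice_graph(n_rows, n_cols)
    sources = np.flatnonzero(boundary.ravel())
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    values = dist.reshape(n_rows, n_cols) * pitch
    sign = np.where(mask & ~boundary, -1.0, 1.0)
    return DistanceField(values=values * sign, pitch=pitch)
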