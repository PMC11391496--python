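"""Proportional thresholding, degree centrality, and its area under the curve.

A weighted connectivity matrix is binarised at each connection density d
(fraction of the n(n-1)/2 possible edges kept, strongest first); a node's
degree centrality (DC) is its count of suprathreshold connections, and
the summary statistic is the trapezoidal area under the degree-vs-density
curve over the default grid 0.05..0.40 in steps of 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "default_density_grid",
    "DegreeCurve",
    "threshold_by_density",
    "degree_centrality",
    "degree_curves",
    "dc_auc",
]


def default_density_grid() -> np.ndarray:
    """Connection densities 5% to 40% in steps of 1% (36 values)."""
    return np.round(np.arange(5, 41) / 100.0, 2)


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("density grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("density grid must be strictly increasing")
    if grid[0] <= 0 or grid[-1] > 1:
        raise ValueError("densities must lie in (0, 1]")
    return grid


@dataclass
class DegreeCurve:
    """Per-node degree at each density, plus the per-node AUC."""

    densities: np.ndarray  # (n_densities,)
    degrees: np.ndarray  # (n_nodes, n_densities)
    auc: np.ndarray  # (n_nodes,)
    region_labels: list[str]


def _edge_order(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Upper-triangle edges sorted by descending weight, ties by (i, j)."""
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    order = np.lexsort((ju, iu, -w))  # primary: weight desc; then i, j asc
    return iu[order], ju[order], len(w)


def _n_edges(d: float, m: int) -> int:
    """Half-up rounding of d*m (the count of edges kept at density d)."""
    return int(np.floor(d * m + 0.5))


def threshold_by_density(
    W: ConnectivityMatrix | np.ndarray, d: float, use_abs: bool = False
) -> np.ndarray:
    """Binarise a weighted matrix, keeping the round(d*M) strongest edges.

    Ranking uses the signed weight by default, so strong negative
    correlations never count as connections; ``use_abs`` ranks by
    magnitude instead. Ties are broken by lexicographic (i, j) order.
    """
    values = W.values if isinstance(W, ConnectivityMatrix) else np.asarray(W, dtype=float)
    if not 0 < d <= 1:
        raise ValueError("density must lie in (0, 1]")
    ranked = np.abs(values) if use_abs else values
    iu, ju, m = _edge_order(ranked)
    k = _n_edges(d, m)
    A = np.zeros_like(values, dtype=int)
    A[iu[:k], ju[:k]] = 1
    A[ju[:k], iu[:k]] = 1
    return A


def degree_centrality(A: np.ndarray) -> np.ndarray:
    """Row sums of a symmetric binary adjacency matrix."""
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    return A.sum(axis=1)


def degree_curves(
    W: ConnectivityMatrix | np.ndarray,
    grid: np.ndarray | None = None,
    use_abs: bool = False,
    region_labels: list[str] | None = None,
) -> DegreeCurve:
    """Degree centrality at every density of the grid, plus the per-node AUC.

    Thresholds are nested (the edge set at a lower density is a subset of
    the edge set at a higher one), so each node's curve is non-decreasing;
    degrees are accumulated incrementally over the sorted edge list.
    """
    if isinstance(W, ConnectivityMatrix):
        region_labels = W.region_labels
        values = W.values
    else:
        values = np.asarray(W, dtype=float)
        if region_labels is None:
            region_labels = [f"node_{i}" for i in range(values.shape[0])]
    grid = _check_grid(default_density_grid() if grid is None else grid)
    n = values.shape[0]
    ranked = np.abs(values) if use_abs else values
    iu, ju, m = _edge_order(ranked)
    degrees = np.zeros((n, len(grid)), dtype=int)
    deg = np.zeros(n, dtype=int)
    prev_k = 0
    for gi, d in enumerate(grid):
        k = _n_edges(float(d), m)
        for e in range(prev_k, k):
            deg[iu[e]] += 1
            deg[ju[e]] += 1
        prev_k = k
        degrees[:, gi] = deg
    auc = dc_auc_from_curves(degrees, grid)
    return DegreeCurve(grid, degrees, auc, list(region_labels))


def dc_auc_from_curves(
    degrees: np.ndarray, grid: np.ndarray, mode: str = "trapezoid"
) -> np.ndarray:
    """Integrate degree over density; ``mode='sum'`` gives the step-sum variant."""
    grid = _check_grid(grid)
    if len(grid) < 2:
        raise ValueError("need at least 2 densities to integrate")
    if mode == "trapezoid":
        return np.trapezoid(degrees, grid, axis=-1)
    if mode == "sum":
        step = float(np.diff(grid).mean())
        return degrees.sum(axis=-1) * step
    raise ValueError(f"unknown AUC mode {mode!r}")


def dc_auc(
    W: ConnectivityMatrix | np.ndarray,
    grid: np.ndarray | None = None,
    use_abs: bool = False,
    mode: str = "trapezoid",
) -> np.ndarray:
    """Per-node AUC of degree centrality over the density grid."""
    grid = _check_grid(default_density_grid() if grid is None else grid)
    curve = degree_curves(W, grid, use_abs)
    if mode == "trapezoid":
        return curve.auc
    return dc_auc_from_curves(curve.degrees, grid, mode)
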