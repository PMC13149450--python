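"""Spatial weight matrices and geometric derivatives.

k-nearest-neighbor weights (the k=6 network used throughout the analysis),
minimum Euclidean distance to the malignant core, concentric annular zones,
and the LOESS-smoothed core-to-margin expression trajectory.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import SpotLattice, WeightMatrix, ZoneAssignment

_DENSE_LIMIT = 2048  # below this, exact dense all-pairs kNN


def knn_weights(
    lattice: SpotLattice, k: int = 6, row_standardize: bool = True
) -> WeightMatrix:
    """k-nearest-neighbor spatial weights (binary, optionally row-standardized).

    Neighbors are the k nearest by Euclidean distance; exact distance ties
    are broken by ascending spot index so the graph is deterministic on
    degenerate lattices. The graph is listwise (asymmetric): i -> j does not
    imply j -> i.
    """
    n = lattice.n_spots
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need more than k={k} spots, got n={n}")
    coords = lattice.coords
    if n <= _DENSE_LIMIT:
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        # stable mergesort on distance preserves ascending-index tie order
        order = np.argsort(d, axis=1, kind="stable")
        nbrs = order[:, :k]
    else:
        tree = cKDTree(coords)
        # over-query to resolve boundary ties deterministically
        kk = min(n, k + 16)
        dist, idx = tree.query(coords, k=kk)
        nbrs = np.empty((n, k), dtype=int)
        for i in range(n):
            cand = [(dist[i, j], idx[i, j]) for j in range(kk) if idx[i, j] != i]
            cand.sort()
            nbrs[i] = [c[1] for c in cand[:k]]
    w = np.full((n, k), 1.0 / k if row_standardize else 1.0)
    return WeightMatrix(n=n, neighbors=nbrs, weights=w, row_standardized=row_standardize)


def min_distance_to_set(lattice: SpotLattice, mask: np.ndarray) -> np.ndarray:
    """Per-spot minimum Euclidean distance to the spots selected by ``mask``.

    Spots inside the set get distance 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != lattice.n_spots:
        raise ValueError("mask length mismatch")
    if not mask.any():
        raise ValueError("mask selects no spots")
    d = cdist(lattice.coords, lattice.coords[mask]).min(axis=1)
    d[mask] = 0.0
    return d


def annular_zones(distances: np.ndarray, zone_width: float) -> ZoneAssignment:
    """Assign each spot to the concentric annulus floor(d / zone_width)."""
    if zone_width <= 0:
        raise ValueError("zone_width must be positive")
    distances = np.asarray(distances, dtype=float)
    if np.any(distances < 0):
        raise ValueError("distances must be nonnegative")
    zone = np.floor(distances / zone_width).astype(int)
    return ZoneAssignment(distances=distances, zone=zone, zone_width=zone_width)


def spatial_lag(W: WeightMatrix, z: np.ndarray) -> np.ndarray:
    """lag_i = sum_j w_ij z_j."""
    return W.lag(z)


def core_margin_profile(
    lattice: SpotLattice,
    core_mask: np.ndarray,
    values: np.ndarray,
    span: float = 0.75,
    n_grid: int = 50,
) -> dict:
    """Core-to-margin trajectory: LOESS of ``values`` against distance-to-core.

    Locally weighted degree-1 regression with tricube weights and no
    robustness iterations, evaluated on a regular distance grid. Returns the
    grid, fitted values, and the raw (distance, value) pairs.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    d = min_distance_to_set(lattice, core_mask)
    outside = ~np.asarray(core_mask, dtype=bool)
    if outside.sum() < 10:
        raise ValueError("need >= 10 spots outside the core for the fit")
    grid = np.linspace(d.min(), d.max(), n_grid)
    fitted = lowess(
        values, d, frac=span, it=0, xvals=grid, is_sorted=False
    )
    return {
        "grid": grid,
        "fitted": np.asarray(fitted, dtype=float),
        "distance": d,
        "values": values,
        "span": span,
    }
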