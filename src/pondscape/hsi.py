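"""Habitat suitability index (HSI) and its diagnostics.

HSI is the cellwise product of the climate-only and land-cover-only
ensemble suitability probabilities — an independence assumption between
the two factors.  Future HSI multiplies the future climate surface by the
*current* land-cover surface (land cover held fixed).  The module also
provides suitable-area summaries and a global Moran's I permutation test
used as the spatial-autocorrelation diagnostic on model residuals at
species locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import distance_matrix

from .raster import GridRaster

__all__ = [
    "HsiSurface",
    "combine_suitability",
    "suitable_area",
    "morans_i",
    "morans_i_test",
    "inverse_distance_weights",
    "rook_weights",
]


@dataclass
class HsiSurface:
    """HSI raster in [0, 1], tagged with species and scenario labels."""

    raster: GridRaster
    species: str = ""
    scenario: str = "current"


def combine_suitability(
    climate: GridRaster, landcover: GridRaster, species: str = "", scenario: str = "current"
) -> HsiSurface:
    """Cellwise product of the two suitability surfaces (aligned fine frames)."""
    climate.require_same_frame(landcover)
    return HsiSurface(
        climate.with_values(climate.values * landcover.values), species, scenario
    )


def suitable_area(hsi: HsiSurface, threshold: float) -> float:
    """Area (km^2) of cells whose HSI is at or above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    vals = hsi.raster.values
    count = int(np.sum(vals >= threshold))
    return count * hsi.raster.cell_area_m2 / 1e6


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


def rook_weights(n_rows: int, n_cols: int, row_standardize: bool = True) -> np.ndarray:
    """Rook-adjacency weight matrix for grid cells in row-major order."""
    n = n_rows * n_cols
    W = np.zeros((n, n))
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    W[i, rr * n_cols + cc] = 1.0
    if row_standardize:
        W = W / W.sum(axis=1, keepdims=True)
    return W


def inverse_distance_weights(points: np.ndarray, row_standardize: bool = True) -> np.ndarray:
    """Inverse-distance weights among point locations (zero diagonal).

    Coincident points get the weight of the smallest positive pairwise
    distance (they are maximally "close").
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    D = distance_matrix(pts, pts)
    pos = D[D > 0]
    if pos.size == 0:
        raise ValueError("all points are coincident")
    floor = pos.min()
    with np.errstate(divide="ignore"):
        W = 1.0 / np.maximum(D, floor)
    np.fill_diagonal(W, 0.0)
    if row_standardize:
        W = W / W.sum(axis=1, keepdims=True)
    return W


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Global Moran's I.

    ``I = (n / W) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with z the
    deviations from the mean and W the total weight; lies in [-1, 1] for
    row-standardised weights.
    """
    x = np.asarray(values, dtype=float).ravel()
    W = np.asarray(weights, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 locations")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I undefined for constant values")
    w_total = float(W.sum())
    return float(n / w_total * (z @ W @ z) / denom)


def morans_i_test(
    values: np.ndarray, weights: np.ndarray, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Two-sided permutation test of Moran's I.

    p = (1 + #{|I_perm| >= |I_obs|}) / (n_perm + 1); p is in (0, 1].
    """
    x = np.asarray(values, dtype=float).ravel()
    i_obs = morans_i(x, weights)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    W = np.asarray(weights, dtype=float)
    n = x.size
    w_total = float(W.sum())
    z = x - x.mean()
    denom = float(z @ z)
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        i_perm = n / w_total * (zp @ W @ zp) / denom
        if abs(i_perm) >= abs(i_obs):
            count += 1
    return i_obs, (1 + count) / (n_perm + 1)
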