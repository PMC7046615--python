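"""Land-cover covariates.

Surface-compactness (SC) rasters for polygonal habitat elements,
distance-to-nearest rasters for point elements (ponds, springs), and the
block disaggregation that brings coarse climate surfaces onto the fine
grid.  Compactness is the isoperimetric quotient 4*pi*A/P^2, equal to 1
for a disc and scale-invariant; SC multiplies it by the patch area so
that both shape and extent enter the covariate.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.strtree import STRtree

from .raster import FrameMismatchError, GridRaster

__all__ = [
    "compactness",
    "sc_index",
    "rasterize_sc",
    "distance_to_nearest",
    "disaggregate",
]


def compactness(patch) -> float:
    """Isoperimetric compactness 4*pi*area/perimeter**2 of a polygon.

    In (0, 1]; equals 1 only for a disc.
    """
    area = patch.area
    perimeter = patch.length
    if perimeter <= 0 or area <= 0:
        raise ValueError("patch must have positive area and perimeter")
    return 4.0 * math.pi * area / perimeter**2


def sc_index(patch) -> float:
    """Surface-compactness index: compactness x area (m^2-scaled)."""
    return compactness(patch) * patch.area


def rasterize_sc(patches, frame: GridRaster) -> GridRaster:
    """Per-cell SC of the patch overlapping the cell center (0 where none).

    Cell membership is decided by cell-center-in-polygon (boundary
    inclusive); when several patches cover a center the first in input
    order wins.
    """
    out = np.zeros(frame.shape)
    patches = list(patches)
    if not patches:
        return frame.with_values(out)
    sc_values = [sc_index(p) for p in patches]
    tree = STRtree(patches)
    xs, ys = frame.cell_centers()
    pts = [Point(x, y) for x, y in zip(xs.ravel(), ys.ravel())]
    flat = out.ravel()
    for i, pt in enumerate(pts):
        hits = sorted(tree.query(pt, predicate="covered_by"))
        if len(hits):
            flat[i] = sc_values[hits[0]]
    return frame.with_values(flat.reshape(frame.shape))


def distance_to_nearest(elements: np.ndarray, frame: GridRaster) -> GridRaster:
    """Euclidean distance (m) from each cell center to the nearest element."""
    elements = np.asarray(elements, dtype=float).reshape(-1, 2)
    if elements.shape[0] == 0:
        raise ValueError("element set is empty: distance field would be infinite")
    xs, ys = frame.cell_centers()
    tree = cKDTree(elements)
    d, _ = tree.query(np.column_stack([xs.ravel(), ys.ravel()]))
    return frame.with_values(d.reshape(frame.shape))


def disaggregate(coarse: GridRaster, fine_frame: GridRaster) -> GridRaster:
    """Block-replicate a coarse raster onto an aligned finer frame.

    Every fine cell takes the value of its containing coarse cell
    (nearest-neighbour disaggregation); the fine cell size must divide the
    coarse cell size exactly and the frames must share an origin.
    """
    ratio = coarse.cell_size / fine_frame.cell_size
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise FrameMismatchError("fine cell size must divide coarse cell size exactly")
    if (
        abs(coarse.origin[0] - fine_frame.origin[0]) > 1e-9
        or abs(coarse.origin[1] - fine_frame.origin[1]) > 1e-9
    ):
        raise FrameMismatchError("frames are not aligned at the origin")
    expected = (coarse.n_rows * factor, coarse.n_cols * factor)
    if fine_frame.shape != expected:
        raise FrameMismatchError(f"fine frame shape {fine_frame.shape} != {expected}")
    values = np.repeat(np.repeat(coarse.values, factor, axis=0), factor, axis=1)
    return fine_frame.with_values(values)
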