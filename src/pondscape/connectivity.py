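"""Interaction-flux connectivity and scenario comparison.

The interaction flux (IF) of patch i is

    IF_i = sum_{j != i} a_i * a_j * exp(-alpha * d_ij)

over graph edges, where a are patch capacities, d_ij least-cost
distances, and alpha the dispersal-kernel decay (exp(-alpha * d_max) =
0.05 at the species' maximum dispersal distance).  IF quantifies each
patch's local contribution to overall connectivity; it ranges from 0
(isolated patch) up to a_i * sum_j a_j.

The patch metric is generalised to every cell by a decreasing weighting
of the patch values with cost distance from patch edges; maps are
z-normalised before the two-species average so that species with
different graphs become comparable, and scenario change is the cellwise
difference of (normalised) maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import LandscapeGraph, ResistanceSurface, cost_distance_map
from .raster import GridRaster

__all__ = [
    "IfResult",
    "ConnectivityMap",
    "interaction_flux",
    "interpolate_metric",
    "normalize_map",
    "combine_species",
    "delta_map",
]


@dataclass
class IfResult:
    """Per-patch interaction flux on a landscape graph."""

    values: np.ndarray  # IF per patch, aligned with graph.patches
    alpha: float
    graph: LandscapeGraph

    def as_dict(self) -> dict[int, float]:
        return {p.id: float(v) for p, v in zip(self.graph.patches, self.values)}


@dataclass
class ConnectivityMap:
    """Gridded connectivity surface tagged with species/scenario labels."""

    raster: GridRaster
    species: str = ""
    scenario: str = "current"
    normalized: bool = False


def interaction_flux(graph: LandscapeGraph) -> IfResult:
    """IF per patch; pruned pairs (no edge) contribute probability 0."""
    n = len(graph.patches)
    out = np.zeros(n)
    caps = {p.id: p.capacity for p in graph.patches}
    index = {p.id: k for k, p in enumerate(graph.patches)}
    for (i, j), d in graph.edges.items():
        p_ij = np.exp(-graph.alpha * d)
        term = caps[i] * caps[j] * p_ij
        out[index[i]] += term
        out[index[j]] += term
    return IfResult(out, graph.alpha, graph)


def interpolate_metric(
    if_result: IfResult,
    frame: GridRaster,
    resistance: ResistanceSurface | None = None,
) -> ConnectivityMap:
    """Spread patch IF values to every cell of the frame.

    Cells inside a patch carry that patch's IF.  Outside, the value is
    the weighted mean of the IF of all patches within the dispersal
    cutoff d_max (in cost distance), with weights exp(-alpha * cost);
    cells beyond d_max of every patch are 0.  An empty patch set yields
    an all-zero map.
    """
    graph = if_result.graph
    if graph.is_empty:
        return ConnectivityMap(frame.with_values(np.zeros(frame.shape)))
    if resistance is None:
        resistance = graph.resistance
    num = np.zeros(frame.shape)
    den = np.zeros(frame.shape)
    inside = np.full(frame.shape, np.nan)
    for patch, if_val in zip(graph.patches, if_result.values):
        costs = cost_distance_map(resistance, patch.cells)
        w = np.where(costs <= graph.d_max, np.exp(-graph.alpha * costs), 0.0)
        num += if_val * w
        den += w
        inside[patch.cells[:, 0], patch.cells[:, 1]] = if_val
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out = np.where(np.isfinite(inside), inside, out)
    return ConnectivityMap(frame.with_values(out))


def normalize_map(cmap: ConnectivityMap) -> ConnectivityMap:
    """Z-score over valid cells (population sd)."""
    vals = cmap.raster.values
    valid = np.isfinite(vals)
    mean = vals[valid].mean()
    sd = vals[valid].std()
    if sd == 0:
        raise ValueError("cannot normalise a constant map")
    return ConnectivityMap(
        cmap.raster.with_values((vals - mean) / sd),
        species=cmap.species,
        scenario=cmap.scenario,
        normalized=True,
    )


def combine_species(maps: list[ConnectivityMap]) -> ConnectivityMap:
    """Cellwise unweighted mean of normalised single-species maps."""
    if not maps:
        raise ValueError("no maps to combine")
    first = maps[0]
    for m in maps[1:]:
        first.raster.require_same_frame(m.raster)
        if m.normalized != first.normalized:
            raise ValueError("maps must share normalization state")
    stack = np.stack([m.raster.values for m in maps])
    return ConnectivityMap(
        first.raster.with_values(stack.mean(axis=0)),
        species="combined",
        scenario=first.scenario,
        normalized=first.normalized,
    )


def delta_map(future: ConnectivityMap, current: ConnectivityMap) -> GridRaster:
    """Future minus current, cellwise; inputs must match frame and state."""
    future.raster.require_same_frame(current.raster)
    if future.normalized != current.normalized:
        raise ValueError("maps must share normalization state")
    return future.raster.with_values(future.raster.values - current.raster.values)
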