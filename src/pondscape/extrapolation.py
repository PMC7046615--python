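"""Multivariate environmental similarity surface (MESS).

Flags where a fitted model is transferred outside its calibration
domain.  Per variable, similarity of a projection value to the reference
distribution (covariate values at the calibration points) is:

* ``f = 0``   (below all reference values): ``100 * (v - min) / (max - min)``
* ``f = 100`` (above all):                  ``100 * (max - v) / (max - min)``
* ``f <= 50``: ``2 f``; otherwise ``2 (100 - f)``

where ``f`` is the percentage of reference values strictly below ``v``.
The surface value of a cell is the minimum over variables; negative
values mark extrapolation (at least one variable outside its reference
range), and the more negative, the more novel the environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .raster import GridRaster

__all__ = ["ReferenceEnvelope", "mess_variable", "mess_surface"]


@dataclass
class ReferenceEnvelope:
    """Sorted per-variable reference (calibration) values."""

    reference: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for name, vals in self.reference.items():
            v = np.sort(np.asarray(vals, dtype=float))
            v = v[np.isfinite(v)]
            if v.size < 2:
                raise ValueError(f"variable {name!r} needs >= 2 reference values")
            if v[0] == v[-1]:
                raise ValueError(f"variable {name!r} has a constant reference")
            clean[name] = v
        self.reference = clean

    @classmethod
    def from_points(
        cls, covariates: Mapping[str, GridRaster], points: np.ndarray
    ) -> "ReferenceEnvelope":
        return cls({name: ras.sample(points) for name, ras in covariates.items()})


def mess_variable(value, ref: np.ndarray):
    """Similarity of value(s) to one sorted reference sample (vectorised)."""
    ref = np.asarray(ref, dtype=float)
    if ref.size == 0 or ref[0] == ref[-1]:
        raise ValueError("reference must be non-empty and non-constant")
    v = np.asarray(value, dtype=float)
    lo, hi = ref[0], ref[-1]
    span = hi - lo
    f = 100.0 * np.searchsorted(ref, v, side="left") / ref.size
    out = np.where(f <= 50.0, 2.0 * f, 2.0 * (100.0 - f))
    out = np.where(f == 0.0, 100.0 * (v - lo) / span, out)
    out = np.where(f == 100.0, 100.0 * (hi - v) / span, out)
    out = np.where(np.isfinite(v), out, np.nan)
    return float(out) if np.isscalar(value) else out


def mess_surface(
    rasters: Mapping[str, GridRaster], envelope: ReferenceEnvelope
) -> GridRaster:
    """Per-cell minimum over variables of the single-variable similarity."""
    names = list(envelope.reference)
    frame = rasters[names[0]]
    acc = np.full(frame.shape, np.inf)
    for name in names:
        ras = rasters[name]
        frame.require_same_frame(ras)
        acc = np.minimum(acc, mess_variable(ras.values, envelope.reference[name]))
    return frame.with_values(acc)
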