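"""Synthetic study landscapes.

Generates study areas with the statistical structure the downstream
analysis assumes: a coarse climate grid (analogue of 1 km cells) carrying
spatially autocorrelated variables, a fine land-cover grid (analogue of
50 x 50 m cells) carrying pond points and habitat polygons, presence
records drawn by weighted sampling from a known "true" logistic
suitability surface, and future-scenario climate grids obtained by
additive shifts of the current variables (land cover is held fixed,
mirroring the no-land-cover-change assumption of the analysis).

Autocorrelated fields are synthesised by Gaussian filtering of white
noise and standardised to zero mean / unit variance; ``autocorr_range``
is the filter sigma in cells.  Every generator is a pure function of
(config, seed): the same seed yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from .raster import GridRaster

__all__ = [
    "SyntheticConfig",
    "TrueSuitabilityModel",
    "ProductSuitability",
    "generate_climate_grids",
    "generate_landcover_layers",
    "sample_occurrences",
    "gaussian_random_field",
]


class SamplingImpossibleError(ValueError):
    """True suitability is zero everywhere: no presence can be drawn."""


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study area.

    Defaults are the desk-scale study conditions used throughout the test
    suite: a 64 x 64 coarse grid refined by a factor 4 (the real analysis
    refines 1 km cells to 50 m, a factor 20, which is emulated at reduced
    scale), three climate and three land-cover variables, autocorrelation
    range 8 cells, 150 ponds and 300 presence records.  Scenario trends are
    additive shifts (in sd units) applied to every climate variable; the
    two defaults emulate a mild and a severe warming trajectory.
    """

    seed: int = 0
    coarse_shape: tuple[int, int] = (64, 64)
    fine_factor: int = 4
    n_climate_vars: int = 3
    n_landcover_vars: int = 3
    autocorr_range: float = 8.0
    lc_autocorr_range: float = 4.0  # fine cells; habitat varies at pond scale
    n_ponds: int = 150
    n_presences: int = 300
    coarse_cell_size: float = 200.0  # fine cells are then 50 m, the local-analysis scale
    trend_magnitudes: dict[str, float] = field(
        default_factory=lambda: {"rcp26_2050": 1.0, "rcp85_2100": 3.0}
    )

    def __post_init__(self) -> None:
        r, c = self.coarse_shape
        if r <= 0 or c <= 0:
            raise ValueError("coarse_shape must be positive")
        if self.fine_factor < 1:
            raise ValueError("fine_factor must be >= 1")
        if min(self.n_climate_vars, self.n_landcover_vars, self.n_ponds, self.n_presences) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def fine_cell_size(self) -> float:
        return self.coarse_cell_size / self.fine_factor

    @property
    def fine_shape(self) -> tuple[int, int]:
        return (self.coarse_shape[0] * self.fine_factor, self.coarse_shape[1] * self.fine_factor)

    def coarse_frame(self) -> GridRaster:
        return GridRaster(
            np.zeros(self.coarse_shape),
            origin=(0.0, self.coarse_shape[0] * self.coarse_cell_size),
            cell_size=self.coarse_cell_size,
        )

    def fine_frame(self) -> GridRaster:
        return GridRaster(
            np.zeros(self.fine_shape),
            origin=(0.0, self.fine_shape[0] * self.fine_cell_size),
            cell_size=self.fine_cell_size,
        )


@dataclass
class TrueSuitabilityModel:
    """Ground-truth logistic suitability used for parameter-recovery tests.

    Suitability = sigmoid(intercept + sum_k coefficients[k] * variable_k);
    values therefore lie in [0, 1] by construction.  The default
    coefficient magnitudes give a sharp niche occupying roughly a tenth
    of the landscape, the discrimination regime in which presence-only
    ensembles typically evaluate well.
    """

    coefficients: dict[str, float]
    intercept: float = -8.0

    def predict(self, covariates: dict[str, GridRaster]) -> GridRaster:
        first = next(iter(covariates.values()))
        eta = np.full(first.shape, self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            covariates[name].require_same_frame(first)
            eta = eta + coef * covariates[name].values
        with np.errstate(over="ignore"):
            return first.with_values(1.0 / (1.0 + np.exp(-eta)))


@dataclass
class ProductSuitability:
    """Product of independent logistic suitability components.

    Mirrors the independence structure of the habitat suitability index
    (climate suitability x land-cover suitability): each component is a
    logistic model on its own covariate subset, and overall suitability
    is their cellwise product.
    """

    components: list[TrueSuitabilityModel]

    def predict(self, covariates: dict[str, GridRaster]) -> GridRaster:
        out = None
        for comp in self.components:
            p = comp.predict({k: covariates[k] for k in comp.coefficients})
            out = p if out is None else out.with_values(out.values * p.values)
        return out


def gaussian_random_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Standardised Gaussian-filtered white noise (mean 0, sd 1)."""
    noise = rng.standard_normal(shape)
    field_ = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    sd = field_.std()
    if sd == 0:
        return field_
    return (field_ - field_.mean()) / sd


def _decorrelated_fields(
    n: int, shape: tuple[int, int], sigma: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """n autocorrelated fields with exactly zero pairwise correlation.

    Raw Gaussian random fields carry chance cross-correlations (the
    effective sample size is the number of autocorrelation ranges, not
    the number of cells); the niche-modelling protocol assumes a set of
    uncorrelated variables, so the fields are orthogonalised over cells
    (QR) and re-standardised.  Linear combinations of smooth fields stay
    smooth, so the spatial structure is preserved.
    """
    if n == 0:
        return []
    raw = np.column_stack(
        [gaussian_random_field(shape, sigma, rng).ravel() for _ in range(n)]
    )
    raw -= raw.mean(axis=0)
    q, r = np.linalg.qr(raw)
    q = q * np.sign(np.diag(r))  # fix reflection ambiguity for determinism
    q = (q - q.mean(axis=0)) / q.std(axis=0)
    return [q[:, j].reshape(shape) for j in range(n)]


def _climate_var_names(config: SyntheticConfig) -> list[str]:
    return [f"clim_{i}" for i in range(config.n_climate_vars)]


def generate_climate_grids(
    config: SyntheticConfig,
) -> dict[str, dict[str, GridRaster]]:
    """Coarse climate rasters per scenario.

    Returns ``{scenario: {variable: GridRaster}}`` with scenario
    ``"current"`` always present; each future scenario is current plus its
    configured additive trend applied to every climate variable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    frame = config.coarse_frame()
    fields = _decorrelated_fields(
        config.n_climate_vars, config.coarse_shape, config.autocorr_range, rng
    )
    current = {
        name: frame.with_values(vals)
        for name, vals in zip(_climate_var_names(config), fields)
    }
    out: dict[str, dict[str, GridRaster]] = {"current": current}
    for scenario, trend in config.trend_magnitudes.items():
        out[scenario] = {
            name: ras.with_values(ras.values + trend) for name, ras in current.items()
        }
    return out


def generate_landcover_layers(config: SyntheticConfig):
    """Fine-grid land-cover covariates, pond points and habitat polygons.

    Returns ``(covariates, ponds, habitat_polygons)`` where covariates is
    ``{name: GridRaster}`` of autocorrelated fields on the fine frame,
    ponds is an (n_ponds, 2) array of uniform random point coordinates
    inside the frame, and habitat_polygons is a list of shapely polygons
    obtained by thresholding one extra autocorrelated field at its 90th
    percentile (patches covering ~10% of cells).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 23]))
    frame = config.fine_frame()
    sigma = config.lc_autocorr_range
    lc_fields = _decorrelated_fields(config.n_landcover_vars, config.fine_shape, sigma, rng)
    covs = {
        f"lc_{i}": frame.with_values(vals) for i, vals in enumerate(lc_fields)
    }

    x0, y0 = frame.origin
    width = frame.n_cols * frame.cell_size
    height = frame.n_rows * frame.cell_size
    ponds = np.column_stack(
        [
            x0 + rng.uniform(0, width, size=config.n_ponds),
            y0 - rng.uniform(0, height, size=config.n_ponds),
        ]
    )

    habitat_field = gaussian_random_field(config.fine_shape, sigma, rng)
    cut = np.percentile(habitat_field, 90.0)
    mask = habitat_field >= cut
    polygons = _mask_to_polygons(mask, frame)
    return covs, ponds, polygons


def _mask_to_polygons(mask: np.ndarray, frame: GridRaster):
    """Union of cell squares of a boolean mask, as a list of polygons."""
    rows, cols = np.nonzero(mask)
    s = frame.cell_size
    x0, y0 = frame.origin
    cells = [
        box(x0 + c * s, y0 - (r + 1) * s, x0 + (c + 1) * s, y0 - r * s)
        for r, c in zip(rows, cols)
    ]
    if not cells:
        return []
    merged = unary_union(cells)
    if merged.geom_type == "Polygon":
        return [merged]
    return list(merged.geoms)


def sample_occurrences(
    true_model: TrueSuitabilityModel,
    covariates: dict[str, GridRaster],
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw ``n`` presence points weighted by true suitability.

    Cells are drawn (with replacement) with probability proportional to
    the true suitability surface; returned coordinates are cell centers,
    shape (n, 2).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37]))
    suit = true_model.predict(covariates)
    p = np.where(np.isfinite(suit.values), suit.values, 0.0).ravel()
    total = p.sum()
    if n > 0 and total <= 0:
        raise SamplingImpossibleError("true suitability is zero everywhere")
    if n == 0:
        return np.empty((0, 2))
    idx = rng.choice(p.size, size=n, p=p / total)
    rows, cols = np.unravel_index(idx, suit.shape)
    xs = np.empty(n)
    ys = np.empty(n)
    for i, (r, c) in enumerate(zip(rows, cols)):
        xs[i], ys[i] = suit.cell_center(r, c)
    return np.column_stack([xs, ys])
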