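"""End-to-end five-step pipeline driver.

Per species: (1) climate-only ensemble niche model on the coarse grid,
projected to each scenario, with MESS transferability maps; (2)
land-cover-only ensemble model on the fine grid (disk pseudo-absences);
(3) HSI = climate x land cover, with the Moran's I residual diagnostic;
(4) binarization, habitat patches, resistance surface and least-cost
landscape graph per scenario; (5) interaction flux, interpolation,
z-normalisation, then the cross-species combination and scenario delta
maps.  A scenario whose suitability collapses to zero patches is recorded
as a "no graph" outcome and the pipeline continues.

Everything is written to a run directory with a machine-readable
manifest (paths + SHA-256 checksums); a rerun with the same config and
seed is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import io as pio
from .config import PipelineConfig
from .connectivity import (
    ConnectivityMap,
    combine_species,
    delta_map,
    interaction_flux,
    interpolate_metric,
    normalize_map,
)
from .enm import EnsembleNicheModel, OccurrenceSet, select_variables
from .extrapolation import ReferenceEnvelope, mess_surface
from .graph import binarization_threshold, build_graph
from .hsi import HsiSurface, combine_suitability, inverse_distance_weights, morans_i_test, suitable_area
from .raster import GridRaster, write_ascii_grid
from .synthetic import (
    ProductSuitability,
    SyntheticConfig,
    TrueSuitabilityModel,
    generate_climate_grids,
    generate_landcover_layers,
    sample_occurrences,
)

__all__ = ["run_pipeline", "true_model_for_species"]

STAGES = ("simulate", "enm", "hsi", "graph", "connectivity", "combine")


def true_model_for_species(config: SyntheticConfig, species_index: int) -> ProductSuitability:
    """Ground-truth niche of the k-th synthetic species.

    The truth is a product of two sharp logistic components — one on the
    climate variables, one on the land-cover variables — mirroring the
    independence structure the HSI combination assumes.  Cool-adapted
    newts: the leading climate variable (a temperature analogue) enters
    negatively, so the additive warming trends of the future scenarios
    reduce suitability; the second species is less climate-sensitive,
    mirroring a species away from its range margin.
    """
    clim_base = [-6.0, 4.0, -3.0]
    lc_base = [5.0, -4.0, 3.0]
    damp = 1.0 - 0.35 * species_index
    clim_coefs = {
        f"clim_{i}": clim_base[i % len(clim_base)] * damp
        for i in range(config.n_climate_vars)
    }
    lc_coefs = {
        f"lc_{i}": lc_base[(i + species_index) % len(lc_base)]
        for i in range(config.n_landcover_vars)
    }
    return ProductSuitability(
        [
            TrueSuitabilityModel(clim_coefs, intercept=-6.0),
            TrueSuitabilityModel(lc_coefs, intercept=-5.0),
        ]
    )


class _Manifest:
    def __init__(self, root: Path):
        self.root = root
        self.artifacts: list[dict] = []
        self.records: dict = {"graphs": {}, "flags": [], "morans_i": {}, "areas": {}}

    def add(self, path: Path, kind: str, species: str = "", scenario: str = "") -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.artifacts.append(
            {
                "path": str(path.relative_to(self.root)),
                "sha256": digest,
                "kind": kind,
                "species": species,
                "scenario": scenario,
            }
        )

    def write(self, config: PipelineConfig) -> Path:
        doc = {
            "seed": config.seed,
            "species": list(config.species),
            "scenarios": config.scenarios,
            "artifacts": sorted(self.artifacts, key=lambda a: a["path"]),
            **self.records,
        }
        path = self.root / "manifest.json"
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
        return path


def _write_raster(man: _Manifest, ras: GridRaster, rel: str, kind: str, species="", scenario="") -> None:
    path = man.root / rel
    path.parent.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(ras, path)
    man.add(path, kind, species, scenario)


def _write_csv(man: _Manifest, df: pd.DataFrame, rel: str, kind: str, species="", scenario="") -> None:
    path = man.root / rel
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    man.add(path, kind, species, scenario)


def run_pipeline(config: PipelineConfig, out_dir: str | Path, through_stage: str = "combine") -> dict:
    """Execute the pipeline, returning the manifest as a dict.

    ``through_stage`` truncates execution after the named stage (one of
    ``simulate``, ``enm``, ``hsi``, ``graph``, ``connectivity``,
    ``combine``).
    """
    if through_stage not in STAGES:
        raise ValueError(f"unknown stage {through_stage!r}")
    last = STAGES.index(through_stage)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = _Manifest(out)
    syn = config.synthetic
    scenarios = config.scenarios

    # ---- stage 1: synthetic study area -------------------------------
    climate = generate_climate_grids(syn)
    lc_fields, ponds, polygons = generate_landcover_layers(syn)
    fine_frame = syn.fine_frame()

    landcover: dict[str, GridRaster] = dict(lc_fields)
    if syn.n_ponds > 0:
        landcover["pond_dist"] = cov.distance_to_nearest(ponds, fine_frame)
    else:
        man.records["flags"].append("no ponds: distance layer omitted")
    if polygons:
        landcover["habitat_sc"] = cov.rasterize_sc(polygons, fine_frame)

    clim_fine_current = {
        name: cov.disaggregate(ras, fine_frame) for name, ras in climate["current"].items()
    }

    occ: dict[str, OccurrenceSet] = {}
    truths: dict[str, TrueSuitabilityModel] = {}
    for k, species in enumerate(config.species):
        truth = true_model_for_species(syn, k)
        truth_covs = {**clim_fine_current, **lc_fields}
        pts = sample_occurrences(truth, truth_covs, syn.n_presences, seed=config.seed * 131 + k)
        occ[species] = OccurrenceSet(species, pts)
        truths[species] = truth
        pio.write_occurrences_csv(occ[species], out / f"{species}_occurrences.csv")
        man.add(out / f"{species}_occurrences.csv", "occurrences", species)

    for scenario, grids in climate.items():
        for name, ras in grids.items():
            _write_raster(man, ras, f"climate/{scenario}/{name}.asc", "climate", scenario=scenario)
    for name, ras in landcover.items():
        _write_raster(man, ras, f"landcover/{name}.asc", "landcover")
    pio.write_points_geojson(ponds, out / "ponds.geojson")
    man.add(out / "ponds.geojson", "ponds")
    pio.write_polygons_geojson(polygons, out / "habitat_polygons.geojson")
    man.add(out / "habitat_polygons.geojson", "habitat-polygons")
    if last == 0:
        man.write(config)
        return json.loads((out / "manifest.json").read_text())

    # ---- stages 2..5 per species -------------------------------------
    e = config.enm
    hsi_maps: dict[str, dict[str, HsiSurface]] = {}
    norm_maps: dict[str, dict[str, ConnectivityMap]] = {}
    graphs_meta = man.records["graphs"]
    for k, species in enumerate(config.species):
        sp_occ = occ[species]
        sp_dir = f"{species}"

        # step 1: climate-only ENM on the coarse grid
        clim_model = EnsembleNicheModel(
            climate["current"],
            sp_occ,
            learners=e.learners,
            n_pa=e.n_pa,
            n_pa_sets=e.n_pa_sets,
            n_runs=e.n_runs,
            pa_method=e.pa_method_climate,
            pa_min_dist=e.pa_min_dist,
            thin_dist=e.thin_dist,
            tss_cutoff=e.tss_cutoff,
            split_fraction=e.split_fraction,
            seed=config.seed * 977 + 2 * k,
        )
        clim_res = clim_model.fit()
        _write_csv(man, clim_res.metrics, f"{sp_dir}/climate_model_metrics.csv", "metrics", species)
        envelope = ReferenceEnvelope.from_points(climate["current"], clim_model.occurrences.points)
        clim_mean: dict[str, GridRaster] = {}
        for scenario in scenarios:
            if scenario == "current":
                mean, cvs = clim_res.mean_surface, clim_res.cv_surface
            else:
                mean, cvs = clim_res.project(climate[scenario])
            clim_mean[scenario] = mean
            mess = mess_surface(climate[scenario], envelope)
            neg_frac = float(np.mean(mess.values[np.isfinite(mess.values)] < 0))
            man.records.setdefault("mess_negative_fraction", {}).setdefault(species, {})[scenario] = neg_frac
            _write_raster(man, mean, f"{sp_dir}/{scenario}/climate_suitability.asc", "climate-suitability", species, scenario)
            _write_raster(man, cvs, f"{sp_dir}/{scenario}/climate_cv.asc", "climate-cv", species, scenario)
            _write_raster(man, mess, f"{sp_dir}/{scenario}/climate_mess.asc", "mess", species, scenario)

        # step 2: land-cover-only ENM on the fine grid, with variable selection
        def fit_landcover(covset):
            return EnsembleNicheModel(
                covset,
                sp_occ,
                learners=e.learners,
                n_pa=e.n_pa,
                n_pa_sets=e.n_pa_sets,
                n_runs=e.n_runs,
                pa_method=e.pa_method_landcover,
                pa_min_dist=e.pa_min_dist,
                thin_dist=e.thin_dist,
                tss_cutoff=e.tss_cutoff,
                split_fraction=e.split_fraction,
                seed=config.seed * 977 + 2 * k + 1,
            ).fit()

        lc_res = fit_landcover(landcover)
        importances = lc_res.variable_importance(n_perm=2, seed=config.seed * 7 + k)
        retained = select_variables(
            lc_res.train_data, importances.to_dict(), corr_threshold=e.corr_threshold
        )
        if len(retained) < len(landcover):
            lc_res = fit_landcover({v: landcover[v] for v in retained})
        man.records.setdefault("landcover_variables", {})[species] = retained
        _write_csv(man, lc_res.metrics, f"{sp_dir}/landcover_model_metrics.csv", "metrics", species)
        _write_csv(
            man,
            importances.rename_axis("variable").reset_index(),
            f"{sp_dir}/landcover_importance.csv",
            "importance",
            species,
        )
        _write_raster(man, lc_res.mean_surface, f"{sp_dir}/landcover_suitability.asc", "landcover-suitability", species)
        _write_raster(man, lc_res.cv_surface, f"{sp_dir}/landcover_cv.asc", "landcover-cv", species)
        if last == 1:
            continue

        # step 3: HSI per scenario (future climate x current land cover)
        hsi_maps[species] = {}
        for scenario in scenarios:
            clim_fine = cov.disaggregate(clim_mean[scenario], fine_frame)
            hsi = combine_suitability(clim_fine, lc_res.mean_surface, species, scenario)
            hsi_maps[species][scenario] = hsi
            _write_raster(man, hsi.raster, f"{sp_dir}/{scenario}/hsi.asc", "hsi", species, scenario)
        uniq = np.unique(sp_occ.points, axis=0)
        resid_u = 1.0 - hsi_maps[species]["current"].raster.sample(uniq)
        W = inverse_distance_weights(uniq)
        i_val, p_val = morans_i_test(resid_u, W, n_perm=199, seed=config.seed * 11 + k)
        man.records["morans_i"][species] = {"I": i_val, "p": p_val}
        if last == 2:
            continue

        # steps 4-5: graphs and connectivity per scenario
        threshold = binarization_threshold(hsi_maps[species]["current"], sp_occ.points)
        norm_maps[species] = {}
        graphs_meta[species] = {}
        areas = {}
        for scenario in scenarios:
            hsi = hsi_maps[species][scenario]
            areas[scenario] = suitable_area(hsi, threshold)
            g = build_graph(
                hsi,
                sp_occ.points,
                dispersal_dist=config.graph.dispersal_dist,
                threshold=threshold,
                p_at_dmax=config.graph.p_at_dmax,
            )
            if g.is_empty:
                graphs_meta[species][scenario] = "no-graph"
                continue
            graphs_meta[species][scenario] = {
                "n_patches": len(g.patches),
                "n_edges": len(g.edges),
                "threshold": g.threshold,
            }
            _write_csv(
                man,
                pd.DataFrame(
                    [(p.id, p.area, p.capacity) for p in g.patches],
                    columns=["id", "area_m2", "capacity"],
                ),
                f"{sp_dir}/{scenario}/patches.csv",
                "patches",
                species,
                scenario,
            )
            _write_csv(
                man,
                pd.DataFrame(
                    [(i, j, c) for (i, j), c in sorted(g.edges.items())],
                    columns=["i", "j", "cost_distance"],
                ),
                f"{sp_dir}/{scenario}/edges.csv",
                "edges",
                species,
                scenario,
            )
            _write_raster(man, g.resistance.raster, f"{sp_dir}/{scenario}/resistance.asc", "resistance", species, scenario)
            if last == 3:
                continue
            flux = interaction_flux(g)
            _write_csv(
                man,
                pd.DataFrame(flux.as_dict().items(), columns=["patch", "IF"]),
                f"{sp_dir}/{scenario}/interaction_flux.csv",
                "if",
                species,
                scenario,
            )
            cmap = interpolate_metric(flux, fine_frame)
            cmap.species, cmap.scenario = species, scenario
            _write_raster(man, cmap.raster, f"{sp_dir}/{scenario}/if_map.asc", "if-map", species, scenario)
            vals = cmap.raster.values[np.isfinite(cmap.raster.values)]
            if vals.std() > 0:
                norm = normalize_map(cmap)
                norm_maps[species][scenario] = norm
                _write_raster(man, norm.raster, f"{sp_dir}/{scenario}/if_map_norm.asc", "if-map-norm", species, scenario)
            else:
                man.records["flags"].append(f"{species}/{scenario}: constant IF map, not normalised")
        man.records["areas"][species] = areas

    # ---- stage: two-species combination and deltas -------------------
    if last >= 5 and norm_maps:
        combined: dict[str, ConnectivityMap] = {}
        for scenario in scenarios:
            per_species = [
                norm_maps[sp][scenario]
                for sp in config.species
                if sp in norm_maps and scenario in norm_maps[sp]
            ]
            if len(per_species) == len(config.species):
                combined[scenario] = combine_species(per_species)
                _write_raster(man, combined[scenario].raster, f"combined/{scenario}/if_combined.asc", "if-combined", "combined", scenario)
            else:
                man.records["flags"].append(f"{scenario}: combination skipped (missing species graph)")
        if "current" in combined:
            for scenario, cmap in combined.items():
                if scenario == "current":
                    continue
                delta = delta_map(cmap, combined["current"])
                _write_raster(man, delta, f"combined/{scenario}/if_delta.asc", "if-delta", "combined", scenario)

    man.write(config)
    return json.loads((out / "manifest.json").read_text())
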