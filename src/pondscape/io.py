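"""Tabular and vector I/O: occurrence CSVs and GeoJSON layers."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

from .enm import OccurrenceSet

__all__ = [
    "read_occurrences_csv",
    "write_occurrences_csv",
    "write_points_geojson",
    "write_polygons_geojson",
    "read_geojson_geometries",
]


def write_occurrences_csv(occ: OccurrenceSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "x", "y"])
        for x, y in occ.points:
            writer.writerow([occ.species_id, repr(float(x)), repr(float(y))])


def read_occurrences_csv(path: str | Path, species: str | None = None) -> OccurrenceSet:
    """Read (species, x, y) rows; a malformed row raises naming its number."""
    pts = []
    species_seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:3]] != ["species", "x", "y"]:
            raise ValueError(f"unexpected occurrence header: {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                sp, x, y = row[0], float(row[1]), float(row[2])
            except (ValueError, IndexError) as err:
                raise ValueError(f"malformed occurrence row {lineno}: {row!r}") from err
            if species is None or sp == species:
                species_seen.add(sp)
                pts.append((x, y))
    sp_id = species if species is not None else (species_seen.pop() if len(species_seen) == 1 else "mixed")
    return OccurrenceSet(sp_id, np.array(pts) if pts else np.empty((0, 2)))


def write_points_geojson(points: np.ndarray, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {},
        }
        for x, y in np.asarray(points).reshape(-1, 2)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def write_polygons_geojson(polygons, path: str | Path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(poly), "properties": {}}
        for poly in polygons
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_geojson_geometries(path: str | Path):
    doc = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in doc["features"]]
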