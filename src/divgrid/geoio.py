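"""Light GeoJSON reading/writing built on shapely.

Country boundaries and protected-area polygons travel as GeoJSON
FeatureCollections; grids and hotspot selections are exported the same
way, with cell indices and areas as feature properties.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .gridding import AnalysisGrid, Cell
from .occurrences import lonlat_to_planar

__all__ = [
    "read_polygons",
    "read_country",
    "write_polygons",
    "grid_to_geojson",
    "selection_to_geojson",
]


def _reproject(geom: BaseGeometry, ref_lon: float, ref_lat: float) -> BaseGeometry:
    from shapely.ops import transform

    def fn(x, y, z=None):
        return lonlat_to_planar(np.asarray(x), np.asarray(y), ref_lon, ref_lat)

    return transform(fn, geom)


def read_polygons(
    path: str | Path,
    projection_ref: tuple[float, float] | None = None,
) -> list[BaseGeometry]:
    """Read all (multi)polygons from a GeoJSON file.

    ``projection_ref = (ref_lon, ref_lat)`` projects WGS84 input to local
    planar metres on load; omit it when the file is already planar.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
    elif doc.get("type") == "Feature":
        geoms = [shape(doc["geometry"])]
    else:
        geoms = [shape(doc)]
    if projection_ref is not None:
        geoms = [_reproject(g, *projection_ref) for g in geoms]
    return geoms


def read_country(
    path: str | Path, projection_ref: tuple[float, float] | None = None
) -> BaseGeometry:
    """Read a country boundary as a single (multi)polygon."""
    geoms = read_polygons(path, projection_ref)
    if not geoms:
        raise ValueError(f"no geometries in {path}")
    return unary_union(geoms)


def write_polygons(
    geoms: Sequence[BaseGeometry],
    path: str | Path,
    properties: Sequence[dict] | None = None,
) -> None:
    feats = []
    for i, g in enumerate(geoms):
        props = properties[i] if properties else {}
        feats.append({"type": "Feature", "geometry": mapping(g), "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def grid_to_geojson(grid: AnalysisGrid, path: str | Path) -> None:
    """Export grid cells as square polygons with index and clipped area."""
    cells = grid.cells
    geoms = [grid.cell_polygon(c) for c in cells]
    props = [
        {"col": c, "row": r, "area_km2": grid.cell_area_km2[(c, r)]}
        for c, r in cells
    ]
    write_polygons(geoms, path, props)


def selection_to_geojson(
    selection, grid: AnalysisGrid, path: str | Path
) -> None:
    """Export a hotspot selection's cells as polygons."""
    cells: list[Cell] = sorted(selection.selected)
    geoms = [grid.cell_polygon(c) for c in cells]
    props = [
        {"col": c, "row": r, "metric": selection.metric, "d": selection.definition}
        for c, r in cells
    ]
    write_polygons(geoms, path, props)
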