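"""Polygon/point helpers: pixel-centre rasterisation and GeoJSON I/O."""

from __future__ import annotations

import json

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .grids import Affine


def polygon_pixel_mask(polygon, grid_shape: tuple[int, int], transform: Affine) -> np.ndarray:
    """Boolean grid of pixels whose *centre* falls inside the polygon."""
    rows, cols = grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = transform.xy(rr.ravel(), cc.ravel())
    inside = shapely.contains_xy(polygon, x, y)
    return inside.reshape(grid_shape)


def write_geojson(features: list[tuple[object, dict]], path) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_geojson(path) -> list[tuple[object, dict]]:
    with open(path) as fh:
        fc = json.load(fh)
    return [(shape(f["geometry"]), f.get("properties", {})) for f in fc["features"]]
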