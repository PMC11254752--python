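"""Minimal single-band raster and vector I/O.

Rasters are written as plain single-band TIFF files with the grid geometry
(origin, pixel size, CRS string) stored as JSON in the TIFF ImageDescription
tag, which keeps the files self-describing and byte-reproducible.  Vector
layers (logging polygons) are exchanged as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

__all__ = ["GridGeometry", "write_raster", "read_raster", "write_polygons", "read_polygons"]


@dataclass(frozen=True)
class GridGeometry:
    """Affine grid geometry of a north-up raster in a local metric CRS.

    ``origin_x, origin_y`` are the coordinates of the *upper-left corner* of
    the upper-left pixel; rows increase southwards.
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    crs: str = "LOCAL_METRIC"

    def pixel_center(self, row, col):
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def rowcol(self, x, y):
        col = np.floor((np.asarray(x) - self.origin_x) / self.pixel_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col


def write_raster(path, array: np.ndarray, geom: GridGeometry, tags: dict | None = None) -> None:
    meta = {"geometry": asdict(geom)}
    if tags:
        meta["tags"] = tags
    tifffile.imwrite(
        Path(path),
        np.asarray(array),
        description=json.dumps(meta, sort_keys=True),
        software=None,  # keep output byte-identical across runs
    )


def read_raster(path) -> tuple[np.ndarray, GridGeometry, dict]:
    with tifffile.TiffFile(Path(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        meta = json.loads(page.description or "{}")
    geom = GridGeometry(**meta.get("geometry", {}))
    return arr, geom, meta.get("tags", {})


def write_polygons(path, polygons, properties=None) -> None:
    """Write shapely polygons (with optional per-feature property dicts) as GeoJSON."""
    features = []
    properties = properties or [{} for _ in polygons]
    for poly, props in zip(polygons, properties):
        features.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, sort_keys=True)


def read_polygons(path):
    with open(path) as fh:
        gj = json.load(fh)
    polys = [shape(f["geometry"]) for f in gj["features"]]
    props = [f.get("properties", {}) for f in gj["features"]]
    return polys, props
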