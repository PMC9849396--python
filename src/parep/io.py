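"""Plain-text readers and writers for the pipeline's file contract.

Rasters are stored as ESRI ASCII grids (``.asc``), polygons as GeoJSON,
tables as CSV and configuration as YAML — all inspectable text formats.
The ASCII-grid convention stores the top row first; in memory row 0 is the
bottom row, so arrays are flipped on the way in and out.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec

NODATA = -9999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec) -> None:
    """Write a raster as an ESRI ASCII grid. NaN cells become nodata."""
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"raster shape {values.shape} != grid shape {grid.shape}")
    out = values.astype(float).copy()
    out[~np.isfinite(out)] = NODATA
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y!r}\n"
        f"cellsize {grid.cell_side!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh, ndmin=2)
    grid = GridSpec(
        n_rows=int(meta["nrows"]),
        n_cols=int(meta["ncols"]),
        cell_side=meta["cellsize"],
        origin_x=meta["xllcorner"],
        origin_y=meta["yllcorner"],
    )
    if data.shape != grid.shape:
        raise ValueError(f"{path}: data shape {data.shape} != header {grid.shape}")
    data = data[::-1].copy()
    nodata = meta.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    return data, grid


def write_geojson(
    path: str | Path,
    geometries: Iterable[BaseGeometry],
    properties: Iterable[dict] | None = None,
) -> None:
    geometries = list(geometries)
    props = list(properties) if properties is not None else [{} for _ in geometries]
    if len(props) != len(geometries):
        raise ValueError("one property dict per geometry required")
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, props)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    with open(path) as fh:
        fc = json.load(fh)
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    props = [f.get("properties") or {} for f in fc["features"]]
    return geoms, props


def write_yaml(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def sanitize_float(x: float) -> float | None:
    """JSON-safe float (NaN/inf → None)."""
    return x if math.isfinite(x) else None
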