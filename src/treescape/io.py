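"""Readers and writers for the pipeline's on-disk artifacts.

Rasters are stored as ESRI ASCII grids (``.asc``) — a plain-text format any
GIS reads — with the grid georeferencing in the header. Vector layers go to
GeoJSON, tables to CSV, trees to Newick, and run manifests to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec

ASC_NODATA = -9999.0


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray, mask: np.ndarray | None = None) -> None:
    """Write a 2-D array on `grid` as an ESRI ASCII grid (row 0 = north)."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"array shape {values.shape} != grid shape {grid.shape}")
    out = values.copy()
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = ASC_NODATA
    out[~np.isfinite(out)] = ASC_NODATA
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min}\n"
        f"yllcorner {grid.lat_min}\n"
        f"cellsize {grid.resolution}\n"
        f"NODATA_value {ASC_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray, np.ndarray]:
    """Read an ESRI ASCII grid; returns (grid, values, valid_mask)."""
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
    res = hdr["cellsize"]
    grid = GridSpec(
        lon_min=hdr["xllcorner"],
        lon_max=hdr["xllcorner"] + ncols * res,
        lat_min=hdr["yllcorner"],
        lat_max=hdr["yllcorner"] + nrows * res,
        resolution=res,
    )
    values = values.reshape(nrows, ncols)
    valid = values != hdr["nodata_value"]
    values = np.where(valid, values, np.nan)
    return grid, values, valid


def write_geojson(path: str | Path, features: list[tuple[BaseGeometry, dict]]) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list[tuple[BaseGeometry, dict]]:
    fc = json.loads(Path(path).read_text())
    return [(shape(f["geometry"]), f.get("properties") or {}) for f in fc["features"]]


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
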