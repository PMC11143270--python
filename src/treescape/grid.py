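"""Geographic grid specification and spherical cell geometry.

All rasters in the package live on a regular lon/lat (WGS84-style, spherical
approximation) grid. Cells are half-open ``[edge, edge + res)`` intervals,
stored row-major from the north-west corner; values are registered at cell
centers. Cell areas use the exact spherical-band formula
``R^2 * dlon * (sin(lat_n) - sin(lat_s))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max : float
        Bounding box in degrees.
    resolution : float
        Cell size in degrees (square cells).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("empty grid extent")
        if self.n_rows <= 1 or self.n_cols <= 1:
            raise ValueError("degenerate grid: need more than one cell per axis")

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        # row 0 is the northernmost band
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) at cell centers."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def cell_of(self, lon, lat):
        """Map coordinates to (row, col); -1 where off-grid.

        Half-open convention: a point exactly on a shared edge belongs to the
        cell whose ``[edge, edge + res)`` interval contains it (east/south for
        lon; the row whose northern edge is the point for lat, mirrored so
        rows count from the north).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        # rows count from the north: row r spans (lat_max-(r+1)*res, lat_max-r*res]
        # mirrored half-open rule derived from floor on (lat - lat_min)
        row_s = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        row = self.n_rows - 1 - row_s
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        col = np.where(ok, col, -1)
        row = np.where(ok, row, -1)
        return row, col

    def cell_areas_km2(self) -> np.ndarray:
        """Per-cell spherical areas, shape (n_rows, n_cols)."""
        res = np.radians(self.resolution)
        lat_n = np.radians(self.lat_max - np.arange(self.n_rows) * self.resolution)
        lat_s = lat_n - res
        band = EARTH_RADIUS_KM**2 * res * (np.sin(lat_n) - np.sin(lat_s))
        return np.repeat(band[:, None], self.n_cols, axis=1)

    def cell_box(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of one cell."""
        x0 = self.lon_min + col * self.resolution
        y1 = self.lat_max - row * self.resolution
        return (x0, y1 - self.resolution, x0 + self.resolution, y1)

    def to_dict(self) -> dict:
        return {
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "resolution": self.resolution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            lon_min=d["lon_min"],
            lon_max=d["lon_max"],
            lat_min=d["lat_min"],
            lat_max=d["lat_max"],
            resolution=d["resolution"],
        )
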