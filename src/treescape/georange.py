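"""Geographic range polygons from native countries and supported observations.

A species' modeling range is the intersection of (a) the union of its native
countries dilated by a large (default 1000 km) buffer and (b) a polygon built
around the ecoregions holding spatially supported observations. Support
requires a minimum number of other occupied cells within a neighbor radius,
which screens out isolated (often erroneous or non-native) records. Small
ecoregions enter whole; large ones only where they lie near observations.
If no observation survives the support rule the buffered native range is
used alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely import Polygon

from ._geo import buffer_km, geodesic_span_km, pairwise_haversine_km
from .grid import GridSpec
from .worldgen import RegionSet

AGGREGATION_LIMIT = 10_000  # observations above this are spatially coarsened
COARSEN_FACTOR = 10


@dataclass
class RangePolygon:
    species_id: str
    geometry: BaseGeometry
    provenance: dict = field(default_factory=dict)


def buffered_native_range(regions: RegionSet, native_ids: set[str], buffer_km_: float = 1000.0) -> BaseGeometry:
    """Union of the named country polygons dilated by a great-circle buffer."""
    lookup = dict(regions.countries)
    unknown = sorted(set(native_ids) - set(lookup))
    if unknown:
        raise KeyError(f"unknown native country id(s): {', '.join(unknown)}")
    if not native_ids:
        raise ValueError("native_ids must be non-empty")
    geoms = [buffer_km(lookup[cid], buffer_km_) for cid in sorted(native_ids)]
    return unary_union(geoms)


def supported_observations(
    cells: np.ndarray,
    grid: GridSpec,
    radius_km: float = 1000.0,
    min_neighbors: int = 3,
) -> np.ndarray:
    """Keep cells with >= min_neighbors other occupied cells within radius_km.

    Distances are great-circle, cell center to cell center.
    """
    cells = np.asarray(cells)
    if len(cells) == 0:
        return cells.reshape(0, 2)
    lon = grid.lon_centers()[cells[:, 1]]
    lat = grid.lat_centers()[cells[:, 0]]
    d = pairwise_haversine_km(lon, lat)
    np.fill_diagonal(d, np.inf)
    keep = (d <= radius_km).sum(axis=1) >= min_neighbors
    return cells[keep]


def ecoregion_support_polygon(
    regions: RegionSet,
    supported_cells: np.ndarray,
    grid: GridSpec,
    near_km: float = 200.0,
    buffer_km_: float = 1000.0,
    small_bbox_km: float = 1000.0,
) -> BaseGeometry:
    """Polygon around ecoregions holding supported observations.

    Small ecoregions (bounding box under ``small_bbox_km`` in width or
    length) are buffered whole; large ones are first clipped to the part
    within ``near_km`` of a supported observation.
    """
    supported_cells = np.asarray(supported_cells).reshape(-1, 2)
    if len(supported_cells) == 0:
        return Polygon()
    eco_of_cell = regions.ecoregion_idx[supported_cells[:, 0], supported_cells[:, 1]]
    lon = grid.lon_centers()[supported_cells[:, 1]]
    lat = grid.lat_centers()[supported_cells[:, 0]]
    pts = MultiPoint(list(zip(lon, lat)))
    parts = []
    for ei in np.unique(eco_of_cell):
        _, eco_geom, _ = regions.ecoregions[int(ei)]
        x0, y0, x1, y1 = eco_geom.bounds
        width, height = geodesic_span_km(x0, y0, x1, y1)
        if width < small_bbox_km or height < small_bbox_km:
            parts.append(buffer_km(eco_geom, buffer_km_))
        else:
            near = buffer_km(pts, near_km)
            clipped = eco_geom.intersection(near)
            if not clipped.is_empty:
                parts.append(buffer_km(clipped, buffer_km_))
    if not parts:
        return Polygon()
    return unary_union(parts)


def _coarsen_cells(cells: np.ndarray, factor: int = COARSEN_FACTOR) -> np.ndarray:
    """Snap cells to a `factor`x coarser grid and deduplicate, keeping one
    representative fine cell (the first in each coarse block)."""
    coarse = cells // factor
    _, first = np.unique(coarse, axis=0, return_index=True)
    return cells[np.sort(first)]


def build_geographic_range(
    regions: RegionSet,
    native_ids: set[str],
    cells: np.ndarray,
    grid: GridSpec,
    species_id: str = "",
    *,
    buffer_km_: float = 1000.0,
    radius_km: float = 1000.0,
    min_neighbors: int = 3,
    near_km: float = 200.0,
    small_bbox_km: float = 1000.0,
) -> RangePolygon:
    """Intersect the buffered native range with the ecoregion-support polygon."""
    cells = np.asarray(cells).reshape(-1, 2)
    aggregated = False
    if len(cells) > AGGREGATION_LIMIT:
        cells = _coarsen_cells(cells)
        aggregated = True
    native = buffered_native_range(regions, native_ids, buffer_km_)
    supported = supported_observations(cells, grid, radius_km, min_neighbors)
    eco_poly = ecoregion_support_polygon(
        regions, supported, grid, near_km, buffer_km_, small_bbox_km
    )
    if eco_poly.is_empty:
        geometry = native
        ecoregions_included = []
    else:
        geometry = native.intersection(eco_poly)
        eco_of_cell = regions.ecoregion_idx[supported[:, 0], supported[:, 1]]
        ecoregions_included = sorted(
            {regions.ecoregions[int(i)][0] for i in np.unique(eco_of_cell)}
        )
    return RangePolygon(
        species_id=species_id,
        geometry=geometry,
        provenance={
            "n_obs_used": int(len(cells)),
            "n_supported": int(len(supported)),
            "ecoregions_included": ecoregions_included,
            "aggregated": aggregated,
        },
    )
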