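"""Range sizes, forest-constrained ranges, and range-reduction statistics.

A species' occupancy range size is the spherical surface area of its binary
distribution. Constraining the map to forested cells (tree cover >= 10% by
default) yields the area-of-habitat analog; the relative reduction
``1 - forest/full`` measures how much historical forest loss restricts the
potential range. Species are assigned to forest biomes when at least 20% of
their distribution falls inside the biome's ecoregions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridSpec
from .sdm import BinaryDistribution
from .worldgen import RegionSet


@dataclass
class RangeRecord:
    species_id: str
    range_km2: float
    forest_range_km2: float
    relative_reduction: float
    biomes: set[str]
    empty_range: bool = False


def range_area(binary: BinaryDistribution, grid: GridSpec | None = None) -> float:
    """Total spherical area (km^2) of suitable cells."""
    grid = grid or binary.grid
    return float(grid.cell_areas_km2()[binary.suitable].sum())


def constrain_to_forest(
    binary: BinaryDistribution, tree_cover: np.ndarray, min_cover: float = 10.0
) -> BinaryDistribution:
    """Retain suitable cells with tree cover >= min_cover percent."""
    if tree_cover.shape != binary.grid.shape:
        raise ValueError("tree cover raster not on the binary map's grid")
    values = binary.values & (tree_cover >= min_cover)
    return BinaryDistribution(grid=binary.grid, values=values, valid=binary.valid)


def assign_biomes(
    binary: BinaryDistribution, regions: RegionSet, min_fraction: float = 0.2
) -> set[str]:
    """Biomes holding at least ``min_fraction`` of the distribution's area."""
    areas = binary.grid.cell_areas_km2()
    suit = binary.suitable
    total = areas[suit].sum()
    if total == 0:
        warnings.warn("empty distribution: no biome assigned", stacklevel=2)
        return set()
    by_biome: dict[str, float] = {}
    for i, (_, _, biome) in enumerate(regions.ecoregions):
        cells = suit & (regions.ecoregion_idx == i)
        by_biome[biome] = by_biome.get(biome, 0.0) + areas[cells].sum()
    return {b for b, a in by_biome.items() if a / total >= min_fraction}


def make_range_records(
    binaries: dict[str, BinaryDistribution],
    tree_cover: np.ndarray,
    regions: RegionSet,
    min_cover: float = 10.0,
    min_fraction: float = 0.2,
) -> pd.DataFrame:
    """Per-species range sizes, forest-constrained sizes, and reductions."""
    rows = []
    for sid in sorted(binaries):
        b = binaries[sid]
        full = range_area(b)
        forest = range_area(constrain_to_forest(b, tree_cover, min_cover))
        if full == 0:
            red = 0.0
        else:
            red = 1.0 - forest / full
        rows.append(
            {
                "species_id": sid,
                "range_km2": full,
                "forest_range_km2": forest,
                "relative_reduction": red,
                "biomes": ";".join(sorted(assign_biomes(b, regions, min_fraction))),
                "empty_range": full == 0,
            }
        )
    return pd.DataFrame(rows)


def median_range_map(
    binaries: dict[str, BinaryDistribution],
    range_records: pd.DataFrame,
    constrained: bool = True,
) -> np.ndarray:
    """Per-cell median range size over the species suitable there.

    Uses the forest-constrained sizes when ``constrained``; cells where no
    species is suitable are NaN. Median of an even count is the midpoint of
    the central pair.
    """
    if not binaries:
        raise ValueError("no binary maps")
    col = "forest_range_km2" if constrained else "range_km2"
    sizes = range_records.set_index("species_id")[col]
    first = next(iter(binaries.values()))
    shape = first.grid.shape
    stack = np.stack([binaries[s].suitable for s in sizes.index])
    vals = sizes.to_numpy()[:, None, None]
    out = np.full(shape, np.nan)
    counts = stack.sum(axis=0)
    any_cells = counts > 0
    rr, cc = np.nonzero(any_cells)
    for r, c in zip(rr, cc):
        out[r, c] = np.median(vals[stack[:, r, c], 0, 0])
    return out


def reduction_test(full_sizes: np.ndarray, forest_sizes: np.ndarray) -> dict:
    """Paired two-sided t-test of full vs forest-constrained range sizes."""
    full_sizes = np.asarray(full_sizes, dtype=float)
    forest_sizes = np.asarray(forest_sizes, dtype=float)
    if len(full_sizes) != len(forest_sizes) or len(full_sizes) < 2:
        raise ValueError("need paired vectors with n >= 2")
    diff = full_sizes - forest_sizes
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return {"t": 0.0, "p": np.nan, "degenerate": True}
        return {"t": np.inf if diff.mean() > 0 else -np.inf, "p": np.nan, "degenerate": True}
    t, p = stats.ttest_rel(full_sizes, forest_sizes)
    return {"t": float(t), "p": float(p), "degenerate": False}


def biome_reduction_summary(range_records: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of relative reduction per biome (type-7 quartiles)."""
    rows = []
    recs = range_records[~range_records["empty_range"]]
    biomes = sorted({b for bs in recs["biomes"] for b in bs.split(";") if b})
    for biome in biomes:
        sel = recs[recs["biomes"].str.contains(biome, regex=False)]
        red = sel["relative_reduction"].to_numpy()
        rows.append(
            {
                "biome": biome,
                "n_species": len(sel),
                "median_reduction": float(np.median(red)),
                "q1": float(np.percentile(red, 25)),
                "q3": float(np.percentile(red, 75)),
            }
        )
    return pd.DataFrame(rows)
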