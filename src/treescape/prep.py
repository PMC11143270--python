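"""Occurrence cleaning, deduplication, grid aggregation, and eligibility filters.

Presence-only records from several source databases are merged, restricted to
an accepted-name checklist, collapsed to exact-coordinate duplicates, then
aggregated to the predictor grid (one record per species per cell; records on
masked cells, e.g. water, are dropped). Species become eligible for modeling
once they retain a minimum number of spatially explicit (distinct-cell)
observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec


@dataclass
class AggregatedOccurrences:
    """Per-species occupied cells on the predictor grid."""

    grid: GridSpec
    cells: dict[str, np.ndarray]  # species_id -> (n, 2) array of (row, col)

    def n_obs(self, species_id: str) -> int:
        return len(self.cells.get(species_id, ()))

    def species(self) -> list[str]:
        return sorted(self.cells)


def merge_and_deduplicate(tables: list[pd.DataFrame], accepted_names: set[str]) -> pd.DataFrame:
    """Concatenate occurrence tables, keep accepted species, drop exact duplicates.

    Duplicates are records with identical (species_id, lon, lat) regardless of
    source database; the first-seen record's source is retained.
    """
    if not accepted_names:
        warnings.warn("accepted_names is empty: all records dropped", stacklevel=2)
    merged = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["species_id", "lon", "lat", "source_db"]
    )
    merged = merged[merged["species_id"].isin(accepted_names)]
    merged = merged.drop_duplicates(subset=["species_id", "lon", "lat"], keep="first")
    return merged.reset_index(drop=True)


def aggregate_to_grid(
    occ: pd.DataFrame, grid: GridSpec, mask: np.ndarray | None = None
) -> AggregatedOccurrences:
    """Collapse records to distinct grid cells; drop off-grid and masked cells."""
    row, col = grid.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    ok = (row >= 0) & (col >= 0)
    if mask is not None:
        on = ok.copy()
        on[ok] = np.asarray(mask, dtype=bool)[row[ok], col[ok]]
        ok = on
    df = pd.DataFrame(
        {"species_id": occ["species_id"].to_numpy()[ok], "row": row[ok], "col": col[ok]}
    ).drop_duplicates()
    cells = {
        sid: g[["row", "col"]].to_numpy()
        for sid, g in df.groupby("species_id", sort=True)
    }
    return AggregatedOccurrences(grid=grid, cells=cells)


def filter_eligible(agg: AggregatedOccurrences, min_obs: int) -> list[str]:
    """Species with at least ``min_obs`` distinct occupied cells, sorted by id."""
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    return sorted(s for s, c in agg.cells.items() if len(c) >= min_obs)
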