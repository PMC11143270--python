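"""Shared fixtures: a small synthetic world and one fitted distribution model.

Everything is generated at test time from fixed seeds; session scope keeps the
expensive pieces (world generation, ensemble fits) to a single execution.
"""

from __future__ import annotations

import numpy as np
import pytest

from treescape import (
    GridSpec,
    generate_env_stack,
    generate_phylogeny,
    generate_regions,
    generate_species_and_occurrences,
    generate_tree_cover,
)
from treescape import georange, prep, sdm

SMALL_GRID = GridSpec(lon_min=-30.0, lon_max=30.0, lat_min=0.0, lat_max=60.0, resolution=0.5)
WORLD_SEED = 7


class WorldFixture:
    def __init__(self):
        self.grid = SMALL_GRID
        self.env = generate_env_stack(SMALL_GRID, WORLD_SEED)
        self.regions = generate_regions(SMALL_GRID, 6, 10, WORLD_SEED)
        (self.truths, self.occurrences, self.plots, self.occupancy) = (
            generate_species_and_occurrences(
                self.env, self.regions, 10, obs_intensity=1.2, seed=WORLD_SEED, n_plots=200
            )
        )
        self.tree_cover = generate_tree_cover(SMALL_GRID, 0.8, 0.3, WORLD_SEED, self.env.mask)
        self.phylo = generate_phylogeny([t.species_id for t in self.truths], WORLD_SEED)
        self.truth_by_id = {t.species_id: t for t in self.truths}


@pytest.fixture(scope="session")
def world():
    return WorldFixture()


@pytest.fixture(scope="session")
def aggregated(world):
    merged = prep.merge_and_deduplicate([world.occurrences], set(world.truth_by_id))
    return prep.aggregate_to_grid(merged, world.grid, world.env.mask)


@pytest.fixture(scope="session")
def eligible(aggregated):
    return prep.filter_eligible(aggregated, 50)


@pytest.fixture(scope="session")
def fitted(world, aggregated, eligible):
    """Range polygon + fitted results for the best-observed species."""
    sid = max(eligible, key=aggregated.n_obs)
    truth = world.truth_by_id[sid]
    rp = georange.build_geographic_range(
        world.regions, truth.native_country_ids, aggregated.cells[sid], world.grid, sid
    )
    model = sdm.SpeciesDistributionModel.from_occurrences(
        aggregated.cells[sid], rp.geometry, world.env, seed=11, species_id=sid
    )
    results = model.fit(seed=13)
    suit, binary = results.predict_map(world.env, rp.geometry, "current")
    return {
        "sid": sid,
        "truth": truth,
        "range": rp,
        "model": model,
        "results": results,
        "suit": suit,
        "binary": binary,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
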