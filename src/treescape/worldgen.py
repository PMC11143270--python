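"""Synthetic world generator.

Builds a self-contained planet — environmental raster stack, country and
ecoregion polygons with biome labels, a species phylogeny, Gaussian-niche
species with presence-only occurrences, an independent presence/absence plot
network, and a tree-cover raster — with the statistical structure the
downstream distribution-modeling and composition analyses assume. Species
niches and per-cell occupancy draws are retained as ground truth so that
model-recovery tests can score predictions against the generating process.

All randomness flows from one top-level seed through named substreams
(``env``, ``regions``, ``phylo``, ``occ``, ``cover``): the same seed gives
bit-identical worlds, and changing e.g. the number of species never perturbs
the environmental layers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box
from shapely.ops import unary_union

from .grid import GridSpec

CLIMATE_VARS = ["mat", "t_season", "annual_p", "p_season", "gsl", "npp"]
SOIL_VARS = ["silt", "coarse", "ph"]
PREDICTORS = CLIMATE_VARS + SOIL_VARS

#: seven forest biomes, assigned to synthetic ecoregions by |latitude| band
BIOME_BANDS = [
    (0.0, 8.0, "Tropical Moist Broadleaf Forests"),
    (8.0, 16.0, "Tropical Dry Broadleaf Forests"),
    (16.0, 23.0, "Tropical Coniferous Forests"),
    (23.0, 35.0, "Mediterranean Forests"),
    (35.0, 45.0, "Temperate Broadleaf Forests"),
    (45.0, 55.0, "Temperate Conifer Forests"),
    (55.0, 90.1, "Boreal Forests"),
]

DEFAULT_GRID = GridSpec(lon_min=-60.0, lon_max=60.0, lat_min=0.0, lat_max=60.0, resolution=0.5)

_SOURCE_DBS = ["gbif_syn", "bien_syn", "museum_syn"]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named child stream of the top-level seed."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 4.0) -> np.ndarray:
    """Spatially correlated noise, unit variance, zero mean."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


@dataclass
class EnvStack:
    """Gridded predictor stack: nine current predictors, elevation, future climate."""

    grid: GridSpec
    layers: dict[str, np.ndarray]  # the nine predictors, current climate
    elevation: np.ndarray
    mask: np.ndarray  # True on land (modeled) cells
    future: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)  # scenario -> climate layers

    def scenario_layers(self, scenario: str) -> dict[str, np.ndarray]:
        """Predictor layers for a scenario; soils are held constant."""
        if scenario == "current":
            return self.layers
        if scenario not in self.future:
            raise KeyError(f"unknown scenario {scenario!r}; have {sorted(self.future)}")
        out = dict(self.layers)
        out.update(self.future[scenario])
        return out

    @property
    def scenarios(self) -> list[str]:
        return ["current", *sorted(self.future)]


@dataclass
class RegionSet:
    """Country and ecoregion tilings of the world plus per-cell label grids."""

    countries: list[tuple[str, object]]  # (id, shapely polygon)
    ecoregions: list[tuple[str, object, str]]  # (id, polygon, biome)
    country_idx: np.ndarray  # per-cell index into countries
    ecoregion_idx: np.ndarray  # per-cell index into ecoregions

    def country_ids(self) -> list[str]:
        return [cid for cid, _ in self.countries]

    def ecoregion_ids(self) -> list[str]:
        return [eid for eid, _, _ in self.ecoregions]

    def biome_of(self) -> dict[str, str]:
        return {eid: biome for eid, _, biome in self.ecoregions}


@dataclass
class SpeciesTruth:
    """Generating-process parameters for one species (ground truth)."""

    species_id: str
    native_country_ids: set[str]
    niche_mean: dict[str, float]
    niche_sd: dict[str, float]
    max_prevalence: float

    def __post_init__(self) -> None:
        if not self.native_country_ids:
            raise ValueError("native_country_ids must be non-empty")
        if any(sd <= 0 for sd in self.niche_sd.values()):
            raise ValueError("niche_sd must be positive")


def generate_env_stack(
    grid: GridSpec,
    seed: int,
    *,
    land_fraction: float = 0.85,
    noise_amplitude: float = 1.0,
    scenarios: dict[str, dict[str, float]] | None = None,
) -> EnvStack:
    """Simulate the nine-predictor stack plus elevation and future climate.

    Climate layers are low-order latitudinal trends plus spatially correlated
    noise; mean annual temperature declines with |latitude|. Future layers are
    the current ones shifted by a configurable warming offset (default +3 degC
    on MAT, up to +/-20% on precipitation); soil layers and elevation are
    shared by all scenarios.
    """
    if grid.n_rows < 20 or grid.n_cols < 20:
        raise ValueError("grid must be at least 20x20 cells")
    if scenarios is None:
        scenarios = {"ssp585": {"warming": 3.0, "precip_change": 0.2}}
    rng = _substream(seed, "env")
    shape = grid.shape
    _, lat = grid.center_mesh()
    alat = np.abs(lat)

    def noise(sigma=4.0, amp=1.0):
        return amp * noise_amplitude * _smooth_field(rng, shape, sigma)

    layers: dict[str, np.ndarray] = {}
    layers["mat"] = 28.0 - 0.45 * alat + noise(amp=1.5)
    layers["t_season"] = 4.0 + 0.65 * alat + noise(amp=1.2)
    layers["annual_p"] = np.clip(2400.0 * np.exp(-alat / 35.0) + noise(amp=220.0), 0.0, None)
    layers["p_season"] = np.clip(60.0 + 25.0 * np.sin(np.radians(lat * 6)) + noise(amp=10.0), 0.0, None)
    layers["gsl"] = np.clip(365.0 - 3.4 * alat + noise(amp=18.0), 0.0, 365.0)
    layers["npp"] = np.clip(0.25 * layers["annual_p"] + 14.0 * layers["mat"] + noise(amp=60.0), 0.0, None)
    layers["silt"] = np.clip(40.0 + noise(sigma=6.0, amp=14.0), 0.0, 100.0)
    layers["coarse"] = np.clip(18.0 + noise(sigma=6.0, amp=9.0), 0.0, 80.0)
    layers["ph"] = np.clip(6.3 + noise(sigma=6.0, amp=0.7), 3.5, 9.5)

    elevation = np.clip(900.0 * np.abs(noise(sigma=5.0)) + 120.0 * noise(sigma=2.0), 0.0, None)
    # lapse-rate coupling so elevation shifts are recoverable from climate
    layers["mat"] = layers["mat"] - 4.5 * elevation / 1000.0

    ocean = _smooth_field(rng, shape, sigma=7.0)
    thresh = np.quantile(ocean, 1.0 - land_fraction)
    mask = ocean >= thresh

    future: dict[str, dict[str, np.ndarray]] = {}
    for name, pars in scenarios.items():
        warming = float(pars.get("warming", 3.0))
        pc = float(pars.get("precip_change", 0.2))
        dp = pc * _smooth_field(rng, shape, sigma=6.0) if pc != 0 else np.zeros(shape)
        dp = np.clip(dp, -abs(pc), abs(pc))
        fut = {
            "mat": layers["mat"] + warming,
            "t_season": layers["t_season"] * (1.0 + 0.02 * warming),
            "annual_p": layers["annual_p"] * (1.0 + dp),
            "p_season": layers["p_season"] * (1.0 + 0.5 * dp),
            "gsl": np.clip(layers["gsl"] + 6.0 * warming, 0.0, 365.0),
            "npp": layers["npp"] * (1.0 + 0.03 * warming),
        }
        future[name] = fut

    return EnvStack(grid=grid, layers=layers, elevation=elevation, mask=mask, future=future)


def _runs_to_polygon(grid: GridSpec, member: np.ndarray):
    """Union of a boolean cell set as a polygon, merging row runs first."""
    rects = []
    for r in range(grid.n_rows):
        row = member[r]
        if not row.any():
            continue
        idx = np.flatnonzero(row)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        y1 = grid.lat_max - r * grid.resolution
        y0 = y1 - grid.resolution
        for run in splits:
            x0 = grid.lon_min + run[0] * grid.resolution
            x1 = grid.lon_min + (run[-1] + 1) * grid.resolution
            rects.append(box(x0, y0, x1, y1))
    return unary_union(rects)


def _voronoi_labels(grid: GridSpec, pts_lon: np.ndarray, pts_lat: np.ndarray) -> np.ndarray:
    lon, lat = grid.center_mesh()
    # planar nearest-seed assignment with a cos(lat) longitude weight
    w = np.cos(np.radians(0.5 * (grid.lat_min + grid.lat_max)))
    d2 = (w * (lon[..., None] - pts_lon)) ** 2 + (lat[..., None] - pts_lat) ** 2
    return np.argmin(d2, axis=-1)


def generate_regions(grid: GridSpec, n_countries: int, n_ecoregions: int, seed: int) -> RegionSet:
    """Tile the world into Voronoi countries and (independently) ecoregions.

    Ecoregion seed points are stratified across the |latitude| biome bands
    present in the grid, so every band that intersects the window holds at
    least one ecoregion whenever ``n_ecoregions`` is at least the number of
    bands; each ecoregion receives the biome of its seed point's band.
    """
    n_cells = grid.n_rows * grid.n_cols
    if n_countries < 1 or n_ecoregions < 1:
        raise ValueError("need at least one country and one ecoregion")
    if n_countries > n_cells or n_ecoregions > n_cells:
        raise ValueError("more regions than grid cells")
    rng = _substream(seed, "regions")

    if n_countries == 1:
        country_idx = np.zeros(grid.shape, dtype=int)
        countries = [("C000", box(grid.lon_min, grid.lat_min, grid.lon_max, grid.lat_max))]
    else:
        clon = rng.uniform(grid.lon_min, grid.lon_max, n_countries)
        clat = rng.uniform(grid.lat_min, grid.lat_max, n_countries)
        country_idx = _voronoi_labels(grid, clon, clat)
        countries = [
            (f"C{i:03d}", _runs_to_polygon(grid, country_idx == i)) for i in range(n_countries)
        ]

    bands = [
        (lo, hi, biome)
        for lo, hi, biome in BIOME_BANDS
        if _band_in_window(grid, lo, hi)
    ]
    elon = rng.uniform(grid.lon_min, grid.lon_max, n_ecoregions)
    elat = np.empty(n_ecoregions)
    biomes = []
    for i in range(n_ecoregions):
        lo, hi, biome = bands[i % len(bands)]
        lo_w, hi_w = _band_window(grid, lo, hi)
        elat[i] = rng.uniform(lo_w, hi_w)
        biomes.append(biome)
    ecoregion_idx = _voronoi_labels(grid, elon, elat)
    ecoregions = [
        (f"E{i:03d}", _runs_to_polygon(grid, ecoregion_idx == i), biomes[i])
        for i in range(n_ecoregions)
    ]
    return RegionSet(
        countries=countries,
        ecoregions=ecoregions,
        country_idx=country_idx,
        ecoregion_idx=ecoregion_idx,
    )


def _band_in_window(grid: GridSpec, lo: float, hi: float) -> bool:
    return _band_window(grid, lo, hi) is not None and True


def _band_window(grid: GridSpec, lo: float, hi: float):
    """Latitude interval(s) of the window whose |lat| falls in [lo, hi)."""
    # consider the northern-hemisphere piece and the southern one
    pieces = []
    a, b = max(lo, grid.lat_min), min(hi, grid.lat_max)
    if a < b:
        pieces.append((a, b))
    a, b = max(lo, -grid.lat_max), min(hi, -grid.lat_min)
    if a < b:
        pieces.append((-b, -a))
    if not pieces:
        return None
    return pieces[0]


def biome_for_latitude(lat: float) -> str:
    alat = abs(lat)
    for lo, hi, biome in BIOME_BANDS:
        if lo <= alat < hi:
            return biome
    return BIOME_BANDS[-1][2]


def generate_phylogeny(species_ids: list[str], seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Simulate a rooted ultrametric Yule tree over the given tips.

    Pure-birth process: starting from the root split, each of the k extant
    lineages splits at rate ``birth_rate``; after the last split the process
    runs one more exponential waiting time so every terminal branch has
    positive length. Depth is rescaled to 1 and tips are assigned to the
    species ids in random order.
    """
    ids = list(species_ids)
    if len(ids) < 2:
        raise ValueError("need at least two species")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate tip labels")
    rng = _substream(seed, "phylo")

    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    tree.seed_node.age_from_root = 0.0  # type: ignore[attr-defined]
    active = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        active.append(child)
    birth = {tree.seed_node: 0.0}
    while len(active) < len(ids):
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        birth[node] = t
        for _ in range(2):
            active.append(node.new_child())
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    depth = t
    order = rng.permutation(len(ids))
    for node, tip_i in zip(active, order):
        node.taxon = taxa.get_taxon(ids[tip_i])
        birth[node] = depth
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        node.edge.length = (birth[node] - birth[node.parent_node]) / depth
    return tree


def _true_suitability(env: EnvStack, truth: SpeciesTruth) -> np.ndarray:
    """Product of independent Gaussian responses over the niche predictors."""
    s = np.ones(env.grid.shape)
    for var, mu in truth.niche_mean.items():
        sd = truth.niche_sd[var]
        z = (env.layers[var] - mu) / sd
        s = s * np.exp(-0.5 * z**2)
    return s


def true_suitability(env: EnvStack, truth: SpeciesTruth, scenario: str = "current") -> np.ndarray:
    """Generating-process suitability under a scenario, scaled to max_prevalence."""
    layers = env.scenario_layers(scenario)
    s = np.ones(env.grid.shape)
    for var, mu in truth.niche_mean.items():
        z = (layers[var] - mu) / truth.niche_sd[var]
        s = s * np.exp(-0.5 * z**2)
    peak = s[env.mask].max() if env.mask.any() else s.max()
    if peak > 0:
        s = s * (truth.max_prevalence / peak)
    return np.clip(s, 0.0, 1.0)


def generate_species_and_occurrences(
    env: EnvStack,
    regions: RegionSet,
    n_species: int,
    obs_intensity: float = 1.0,
    seed: int = 0,
    *,
    niche_breadth_range: tuple[float, float] = (0.2, 0.5),
    prevalence_range: tuple[float, float] = (0.8, 0.98),
    niche_vars: list[str] | None = None,
    n_plots: int = 300,
):
    """Draw species niches, presence-only occurrences, and a plot network.

    Each species gets an anchor cell inside its native countries; its niche
    means are the anchor's climate values and its per-predictor sd is a
    breadth factor times the layer's spatial sd. A cell is occupied with
    probability equal to the true suitability (scaled so the best native cell
    sits at ``max_prevalence``); occupied cells yield ``1 + Poisson`` records
    jittered within the cell. Plots re-use the same occupancy draws, so the
    plot network is a noiseless census of the generating process at its cells.

    Returns ``(truths, occurrences, plots, occupancy)`` where ``occupancy``
    is the boolean species x row x col ground-truth occupancy array.
    """
    import pandas as pd

    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = _substream(seed, "occ")
    grid = env.grid
    if niche_vars is None:
        niche_vars = list(CLIMATE_VARS)
    land = env.mask
    lonc, latc = grid.center_mesh()
    n_countries = len(regions.countries)

    truths: list[SpeciesTruth] = []
    occupancy = np.zeros((n_species,) + grid.shape, dtype=bool)
    rec_species, rec_lon, rec_lat, rec_src = [], [], [], []

    layer_sd = {v: env.layers[v][land].std() for v in niche_vars}

    for i in range(n_species):
        sid = f"sp{i:03d}"
        k_native = int(rng.integers(1, max(2, min(n_countries, 4)) + 1))
        native_idx = rng.choice(n_countries, size=min(k_native, n_countries), replace=False)
        native_ids = {regions.countries[j][0] for j in native_idx}
        native_mask = np.isin(regions.country_idx, native_idx) & land
        if not native_mask.any():
            native_mask = land
            native_ids = set(regions.country_ids())
        cells = np.flatnonzero(native_mask.ravel())
        anchor = cells[rng.integers(len(cells))]
        ar, ac = np.unravel_index(anchor, grid.shape)
        breadth = float(np.exp(rng.uniform(np.log(niche_breadth_range[0]), np.log(niche_breadth_range[1]))))
        niche_mean = {v: float(env.layers[v][ar, ac]) for v in niche_vars}
        niche_sd = {v: float(max(breadth * layer_sd[v], 1e-6)) for v in niche_vars}
        prev = float(rng.uniform(*prevalence_range))
        truth = SpeciesTruth(sid, native_ids, niche_mean, niche_sd, prev)
        truths.append(truth)

        suit = true_suitability(env, truth)
        p = np.where(native_mask, suit, 0.0)
        occ = rng.random(grid.shape) < p
        occupancy[i] = occ
        rr, cc = np.nonzero(occ)
        if len(rr) == 0:
            continue
        extra = rng.poisson(max(obs_intensity - 1.0, 0.0), size=len(rr))
        reps = 1 + extra
        rr = np.repeat(rr, reps)
        cc = np.repeat(cc, reps)
        jlon = lonc[rr, cc] + (rng.random(len(rr)) - 0.5) * grid.resolution
        jlat = latc[rr, cc] + (rng.random(len(rr)) - 0.5) * grid.resolution
        rec_species.extend([sid] * len(rr))
        rec_lon.extend(jlon.tolist())
        rec_lat.extend(jlat.tolist())
        rec_src.extend(rng.choice(_SOURCE_DBS, size=len(rr)).tolist())

    occurrences = pd.DataFrame(
        {"species_id": rec_species, "lon": rec_lon, "lat": rec_lat, "source_db": rec_src}
    )

    land_cells = np.flatnonzero(land.ravel())
    n_plots = min(n_plots, len(land_cells))
    plot_cells = rng.choice(land_cells, size=n_plots, replace=False)
    pr, pc = np.unravel_index(plot_cells, grid.shape)
    plot_rows = []
    for j in range(n_plots):
        for i, truth in enumerate(truths):
            plot_rows.append(
                (f"plot{j:04d}", lonc[pr[j], pc[j]], latc[pr[j], pc[j]], truth.species_id,
                 bool(occupancy[i, pr[j], pc[j]]))
            )
    plots = pd.DataFrame(plot_rows, columns=["plot_id", "lon", "lat", "species_id", "present"])
    return truths, occurrences, plots, occupancy


def generate_tree_cover(
    grid: GridSpec,
    base_cover: float = 0.8,
    deforestation_frac: float = 0.3,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Percent tree cover: a deforestation_frac share of land cells below 10%.

    The deforested count is exact by construction: ``round(frac * n_land)``
    cells drawn without replacement get cover in [0, 10); all other land
    cells get cover >= 10 centred on ``base_cover`` of the 10-100 range.
    """
    if not (0.0 <= base_cover <= 1.0 and 0.0 <= deforestation_frac <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    rng = _substream(seed, "cover")
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    cover = np.zeros(grid.shape)
    noise = np.clip(base_cover + 0.15 * _smooth_field(rng, grid.shape, sigma=4.0), 0.0, 1.0)
    cover[mask] = 10.0 + 90.0 * noise[mask]
    land_cells = np.flatnonzero(mask.ravel())
    n_def = int(round(deforestation_frac * len(land_cells)))
    if n_def > 0:
        chosen = rng.choice(land_cells, size=n_def, replace=False)
        flat = cover.ravel()
        flat[chosen] = rng.uniform(0.0, 10.0, size=n_def)
        cover = flat.reshape(grid.shape)
    return cover
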