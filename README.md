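# treescape

A desk-scale pipeline for mapping tree species distributions, forest
composition, and climate-change response on a fully synthetic world.

## The problem

Global analyses of forest biodiversity chain together several methods:
species distribution models (SDMs) fitted to presence-only occurrence
records with sampled pseudoabsences, geographic range polygons that restrict
predictions to a species' native region, community ordinations that map
taxonomic and phylogenetic composition, area-of-habitat calculations that
intersect potential ranges with remotely sensed tree cover, and
ecoregion-level projections of range shifts under future climate. Each step
carries precise rules (training-data schedules, thresholding conventions,
eligibility filters) that are hard to validate against terabyte-scale real
inputs.

`treescape` implements this whole chain against a synthetic planet whose
generating process is known exactly — Gaussian climate niches, Bernoulli
per-cell occupancy, Voronoi countries and ecoregions with latitude-band
biomes, a Yule phylogeny — so every stage can be tested for parameter
recovery, not just for running to completion. It is aimed at method
developers and reviewers who need a transparent, reproducible testbed for
macroecological pipelines.

## The model

For one species with `n_obs` aggregated (distinct-cell) observations:

- **Training schedule.** Presences and uniformly sampled pseudoabsences
  inside the species' range polygon, capped at 20,000 points:
  `n_obs >= 10,000 -> (10,000, 10,000)`; `1818 <= n_obs < 10,000 ->
  (n_obs, 20,000 - n_obs)`; `500 <= n_obs < 1818 -> (n_obs, 10 n_obs)`;
  `n_obs < 500 -> (n_obs, 5000)`.
- **Range polygon.** (native countries ⊕ 1000 km) ∩ (polygon around
  ecoregions holding observations with ≥ 3 neighbours within 1000 km).
- **Ensemble.** Two random forests and two gradient-boosted tree
  classifiers of differing complexity; the suitability map is the mean of
  the four member probabilities, using at most `floor(n_obs / 10)` of the
  nine climate/soil predictors.
- **Binarization.** Threshold chosen by pooled 3-fold cross-validation
  maximizing the true skill statistic, `TSS(t) = sensitivity(t) +
  specificity(t) - 1`; a cell is suitable when `p >= t`.
- **Composition.** Sites × species incidence on an equal-area ~100 km grid;
  taxonomic ordination by 3-axis NMDS (Kruskal stress-1) of Sorensen
  distances; phylogenetic ordination by PCA of the branch-expanded,
  branch-length-weighted, Hellinger-transformed matrix (evoPCA).
- **Occupancy.** Range size = spherical area of suitable cells; the
  area-of-habitat analog restricts to cells with ≥ 10% tree cover;
  relative reduction = `1 - forest / full`.
- **Climate response.** Per forest ecoregion: fractions of species lost and
  gained, median |latitude| and elevation shifts of persisting species, and
  composition change as the Euclidean distance between current and future
  rows in scaled ordination space; biomes compared by Pillai's trace MANOVA.

## Worked example

```python
from treescape import (generate_env_stack, generate_regions,
                       generate_species_and_occurrences)
from treescape import georange, prep, sdm
from treescape.worldgen import DEFAULT_GRID

env = generate_env_stack(DEFAULT_GRID, seed=1)
regions = generate_regions(DEFAULT_GRID, n_countries=8, n_ecoregions=14, seed=1)
truths, occ, plots, occupancy = generate_species_and_occurrences(
    env, regions, n_species=25, seed=1)

merged = prep.merge_and_deduplicate([occ], {t.species_id for t in truths})
agg = prep.aggregate_to_grid(merged, DEFAULT_GRID, env.mask)
sid = prep.filter_eligible(agg, min_obs=200)[0]
truth = next(t for t in truths if t.species_id == sid)

rp = georange.build_geographic_range(
    regions, truth.native_country_ids, agg.cells[sid], DEFAULT_GRID, sid)
model = sdm.SpeciesDistributionModel.from_occurrences(
    agg.cells[sid], rp.geometry, env, seed=2, species_id=sid)
results = model.fit(seed=3)
print(results.summary())
```

prints (seed-exact):

```
Species distribution model sp000
================================================
observations (distinct cells): 202
presences in training:         202
pseudoabsences in training:    5000
predictors (9):               mat, t_season, annual_p, p_season, gsl, npp, silt, coarse, ph
ensemble members:              rf_simple, rf_complex, gbt_simple, gbt_complex
max-TSS threshold:             0.0329
cross-validated TSS:           0.7567
cross-validated AUC:           0.9454
```

The species has 202 distinct occupied cells, so the schedule pairs them
with 5000 pseudoabsences and all nine predictors are allowed (202 ≥ 90).
The cross-validated AUC of 0.95 says the ensemble separates presences from
background almost perfectly; the low max-TSS threshold (0.033) is typical
for a low-prevalence species, where sensitivity is bought cheaply.
`results.predict_map(env, rp.geometry, "ssp585")` then yields the
suitability and binary occupancy rasters under the warmed scenario.

The same run, end to end, from a shell:

```bash
treescape run --out runs/demo --seed 1
```

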