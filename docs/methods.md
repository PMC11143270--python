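# Methods

This note documents the models, the synthetic-world generating process, the
numerical choices, and the known limitations of `treescape`. It is the
package's own account of its science; every number quoted here is computed
by the test suite or by `scripts/acceptance.py`, not asserted from memory.

## 1. The synthetic world

The generator builds a planet whose ground truth is fully known, so the
pipeline's statistical machinery can be scored against the process that
produced its inputs.

**Grid.** A regular lon/lat grid (default 0.5° over a 60° × 120° window,
longitude −60…60, latitude 0…60). Cells are half-open `[edge, edge + res)`
intervals, row-major from the north-west corner; cell areas use the exact
spherical-band formula `R² Δλ (sin φ_N − sin φ_S)` with R = 6371.0088 km.
The latitude window spans all seven forest-biome bands while keeping cell
counts at desk scale (28,800 cells).

**Environment.** Nine predictors — six climate (mean annual temperature,
temperature seasonality, annual precipitation, precipitation seasonality,
growing-season length, net primary productivity) and three soil (silt,
coarse fragments, pH) — plus elevation. Climate layers are low-order
latitudinal trends plus spatially correlated Gaussian noise (FFT-free:
Gaussian-filtered white noise, σ = 4 cells); temperature declines with
|latitude| at 0.45 °C/degree and with elevation at 4.5 °C/km, so both
latitudinal and elevational range shifts are recoverable from climate
alone. A smooth ocean field masks 15% of cells by default. Future
scenarios shift the six climate layers only (default: +3 °C on
temperature, up to ±20% on precipitation, correlated spatially); soils and
elevation are shared by all scenarios, and a zero-warming scenario is
bit-identical to the current climate.

**Regions.** Countries are Voronoi cells of uniform random seed points in
the window (planar nearest-seed assignment with a cos-latitude longitude
weight); ecoregions are an independent Voronoi tiling whose seed points are
stratified across the |latitude| bands, each ecoregion inheriting its
band's biome: tropical moist (<8°), tropical dry (8–16°), tropical conifer
(16–23°), Mediterranean (23–35°), temperate broadleaf (35–45°), temperate
conifer (45–55°), boreal (≥55°). Stratification guarantees at least one
ecoregion per band whenever the count allows.

**Species.** Each species draws 1–4 native countries, an anchor cell inside
them, and an independent-Gaussian niche on the six climate predictors: the
niche mean is the anchor's climate, the per-predictor sd is a breadth
factor (log-uniform in 0.2–0.5) times the layer's spatial sd. True
suitability is the product of the Gaussian responses, rescaled so the best
native cell equals the species' peak prevalence (uniform in 0.8–0.98).
Occupancy is a per-cell Bernoulli draw of that suitability restricted to
native countries; every occupied cell emits one or more (1 + Poisson)
records jittered within the cell. A plot network of randomly chosen cells
censuses the same occupancy draws, emulating an independent
presence–absence survey with perfect detection.

*Why steep niches and near-saturated peak occupancy?* The generator is
required to make its own species recoverable: with broader niches or lower
prevalence, even the true suitability scored against its own Bernoulli
draws has AUC well below 0.95 (the label noise is irreducible), leaving no
headroom for any fitted model. The chosen defaults give a bimodal
suitability field — most cells near zero, the niche core near saturation —
for which the recovery ceiling is high and the fitted ensemble lands at
held-out AUC ≈ 0.93. The price is that the default world rarely produces
the very large (>1818-cell) occurrence counts; tests of the training
schedule's upper regimes use a widened-breadth fixture configuration
instead. A related consequence: the rank correlation between total
occurrence density and generating intensity is capped near 0.45 at the
defaults (sparse Bernoulli ties), so the density-tracking property is
asserted strictly (>0.5) on a broad-niche configuration and directionally
(>0.25) at the defaults.

**Tree cover and phylogeny.** Tree cover assigns an exact
`round(frac · n_land)` subset of land cells a value below 10% (uniform
0–10) and all others ≥10%, centred on a base-cover parameter. The
phylogeny is a unit-depth Yule (pure-birth) tree simulated directly —
waiting times Exp(kλ) between splits, one extra waiting time after the
last split so every terminal branch is strictly positive — and serialized
through dendropy's Newick writer.

All randomness flows from one top-level seed through named substreams
(`env`, `regions`, `phylo`, `occ`, `cover`): identical seeds give
bit-identical worlds, and changing one component's parameters never
perturbs another's draws.

## 2. Occurrence preparation and ranges

Records are merged across source tables, restricted to an accepted-name
list, deduplicated on exact (species, lon, lat), then aggregated to one
record per grid cell; records on masked (water) cells or off-grid are
dropped. Cell assignment uses `floor((coord − origin)/res)` with half-open
cells — a point on a shared edge belongs to the cell whose interval starts
there. Species need ≥20 distinct cells to be modeled and (by default) ≥90
to enter downstream analyses.

The range polygon intersects (a) the union of native-country polygons
dilated by 1000 km with (b) a polygon around ecoregions containing
*supported* observations — cells with at least 3 other occupied cells
within 1000 km great-circle. Small ecoregions (bounding box under 1000 km
in either great-circle span) are buffered whole; larger ones only where
they lie within 200 km of a supported observation. Kilometre buffering
projects the geometry into a local azimuthal-equidistant frame at its
centroid, buffers in the plane, and inverts; the buffered boundary sits
within ±0.5% of the nominal distance at 1000 km for mid-latitude fixtures
(asserted by test). Above 10,000 observations the cells are snapped to a
10× coarser grid before range construction (`provenance.aggregated`
records this). If no observation survives the neighbour rule the buffered
native range is used alone. The 200-km proximity test uses supported
observations only.

## 3. The distribution model

`SpeciesDistributionModel` holds a `TrainingSet` (presences, uniform
pseudoabsences excluding presence cells, both clipped to the range and the
land mask, sized by the training schedule; total capped at 20,000).
`fit()` performs, in order: predictor selection (k = min(9, ⌊n_obs/10⌋);
when k < 9, ranked by impurity importance from one all-predictor random
forest, ties broken by fixed predictor order), threshold optimization, and
a final refit on the full training set, returning `SDMResults`.

The ensemble members are two random forests (150 trees at depth 5; 300
trees unbounded) and two histogram gradient-boosted tree classifiers (100
rounds at depth 2; 300 rounds at depth 5) — "simple" and "complex"
variants of each family, all configurable per model. These sizes are
deliberately desk-scale: they keep a full species fit (3 CV folds plus the
final refit, ~5–6k training points) around 10–15 s on one CPU while
leaving cross-validated AUC ≈ 0.93 on the default world.

Thresholding: folds are assigned at random (redrawn, bounded, until each
holds both classes); out-of-fold ensemble probabilities are pooled; TSS is
scanned over the sorted unique pooled probabilities (this is exact — TSS
is piecewise constant between scores) and the smallest maximizer is kept.
AUC is computed on the same pooled scores. Prediction applies scenario
climate with constant soils, clips to the range polygon (nodata outside),
and binarizes with the `p ≥ t` convention.

Evaluation utilities: confusion-matrix skill against the plot network
(plots outside the range excluded; species with <5 in-range presences
skipped), IoU between binary maps, and `holdout_recovery`, which reserves
20% of a species' occupied cells (shielded from pseudoabsence sampling,
together with a background evaluation sample) and scores the fitted
suitability against the true occupancy on cells the model never saw.

## 4. Ordinations

The community matrix samples each binary map at the centers of an
equal-area coarse grid (columns of constant longitude width, rows of
constant sin-latitude width, sized to the requested cell area — a
projection-free stand-in for an equal-area CRS). Sites on masked centers
or with zero species are dropped; all-zero species columns are retained.

*NMDS.* Kruskal stress-1 with primary (ties-allowed) monotone regression:
disparities are the isotonic regression of configuration distances on the
observed-dissimilarity rank order (secondary sort by current distance),
iterated with the Guttman transform. Twenty starts by default — one from
classical metric scaling, the rest random — keeping the best final
configuration, which therefore never exceeds the metric start's stress;
convergence when the stress improvement drops below 1e-6, with a warning
flag if no start converges. Axes are centered and rotated to principal
axes (distance-preserving). The returned stress equals an independent
pool-adjacent-violators recomputation to 1e-8 (asserted by test).

*evoPCA (Hellinger).* The incidence matrix is expanded to branches
(`B[s,b]` = summed incidence of tips under branch b over all non-root
edges), transformed entry-wise to `sqrt(l_b B_sb / Σ_b' l_b' B_sb')`, and
decomposed by centered PCA; the first three component scores and their
variance fractions are returned. For a star tree with equal branch lengths
this reduces exactly to the plain Hellinger PCA of the species matrix —
the oracle equivalence the tests assert via principal angles.

Post-processing: RGB maps rescale each axis between its 10th and 90th
percentiles (clipped; constant axes map to mid-channel with a warning); a
single-pass interquartile filter removes sites outside [Q1 − IQR, Q3 + IQR]
on any axis (quartiles deliberately not recomputed); k-means with
silhouette-selected k (ties to smaller k); redundancy analysis is
multivariate linear regression of the axes on standardized predictors with
adjusted R², partitioned over the six-climate and three-soil blocks by the
standard partial-R² identities (the shared fraction may go slightly
negative after adjustment and is reported as computed); environmental PCA
standardizes the nine predictors and returns two axes.

## 5. Occupancy and climate response

Range sizes sum exact spherical cell areas over suitable cells. The forest
constraint keeps cells with tree cover ≥ `min_cover` (default 10%,
boundary inclusive); relative reduction is `1 − forest/full`, defined as 0
(flagged) for empty ranges. Species join a biome when ≥20% of their
suitable area falls inside its ecoregions. The median-range map takes, per
cell, the median (midpoint convention for even counts) of the
forest-constrained sizes of the species suitable there. The
unrestricted-vs-restricted comparison is a paired two-sided t-test on the
per-species size differences (pairing is the natural structure; degenerate
zero-variance differences are flagged rather than tested).

Climate response compares current and future binary maps per ecoregion:
membership is ≥1 suitable cell center inside the ecoregion (cell-label
assignment; centers on shared boundaries belong to exactly one region);
fractions lost/gained are set arithmetic over the current set; latitude
and elevation shifts are differences of whole-range medians per persisting
species, summarized by the ecoregion median of |Δlat| and signed Δelev
(whole-range, not clipped to the ecoregion — one shift per species is
computed first, matching the per-species-then-aggregate order).
Composition change ordinates the stacked current+future ecoregion × species
matrix (NMDS on Sorensen; evoPCA), scales each axis to zero mean and unit
variance across all rows, and reports the Euclidean distance between an
ecoregion's current and future rows. Two numerical guards matter here:
identical incidence rows are deduplicated before the NMDS (primary tie
handling would otherwise be free to embed zero-dissimilarity pairs apart,
breaking the zero-delta null), and axes with numerically zero variance are
dropped from the distance rather than scaled up from float noise.

Biome summaries report type-7 quartiles, 1.5·IQR whiskers (most extreme
point within the fence), means, and t-based 95% CIs (undefined for
single-ecoregion biomes). Pillai's trace is computed directly —
V = Σ λᵢ/(1+λᵢ) over the eigenvalues of E⁻¹H from the between/within SSCP
matrices, with the standard F approximation — and is cross-checked against
statsmodels' MANOVA to 1e-9 in the tests; zero-variance metrics are
dropped (with a warning) before the test, and a fully degenerate response
matrix returns the null result (V = 0, p = 1) rather than a singular
solve. For one metric and two groups the F statistic equals the squared
two-sample t statistic exactly.

## 6. Pipeline, formats, and problem sizes

Stages (`synth → prep → range → sdm → ordinate → occupancy → climate`)
communicate only through on-disk text artifacts: ESRI ASCII grids for
rasters, GeoJSON for polygons, CSV for tables, Newick for the tree, JSON
manifests. Each stage is keyed by a hash of its config block chained with
the upstream keys; unchanged stages with intact outputs are skipped, so
deleting one stage's outputs recomputes only it and its dependents, and
identical configs give identical artifact checksums even in fresh
directories.

Default problem sizes are chosen for a single CPU: the smoke pipeline uses
a 0.5° 60°×120° world with ~10 species (<1 min end to end); the recovery
experiment fits ten species on the full default world (~2–3 min); the
acceptance script completes in under five minutes. All sizes are config
entries, not constants.

## 7. What passing tests do and do not show

The synthetic world is deliberately simpler than real data: niches are
independent-Gaussian on the true predictors (no interactions, no missing
covariates), occupancy is at equilibrium with climate (no dispersal lag,
no biotic exclusion), observation effort is spatially uniform within
native countries (no collection bias), plots have perfect detection, the
phylogeny is exactly known, and countries/ecoregions are convex-ish
Voronoi cells. Passing recovery tests therefore demonstrates that the
pipeline's estimators are consistent with their own assumptions — correct
wiring, correct rules, correct statistics — not that the same skill would
be achieved on real occurrence databases, whose biases the generator does
not emulate. Headline numbers from real-data studies (global medians,
stress values, site counts) are not reproduction targets of this package.
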