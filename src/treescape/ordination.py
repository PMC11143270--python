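"""Taxonomic and phylogenetic ordination of the modeled communities.

The binary distribution maps are sampled onto an equal-area coarse grid to
form a sites x species incidence matrix. Taxonomic structure is summarized
by 3-axis non-metric multidimensional scaling (NMDS, Kruskal stress-1) of
Sorensen distances; phylogenetic structure by a Hellinger-transformed,
branch-length-weighted PCA of the branch-expanded incidence matrix (the
"evoPCA" family of phylogenetic beta-diversity ordinations). Downstream
utilities map axes to RGB, remove interquartile-range outliers, cluster the
axes with silhouette-selected k, and relate axes to the environment through
redundancy analysis with climate/soil variation partitioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import silhouette_score

from .grid import EARTH_RADIUS_KM, GridSpec
from .sdm import BinaryDistribution
from .worldgen import CLIMATE_VARS, SOIL_VARS

KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


# ---------------------------------------------------------------------------
# community matrix on an equal-area coarse grid

@dataclass
class CommunityMatrix:
    """Sites x species incidence with site coordinates."""

    sites: pd.DataFrame  # site_id, lon, lat
    incidence: np.ndarray  # (n_sites, n_species) 0/1
    species: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def equal_area_sites(grid: GridSpec, coarse_cell_km: float = 100.0) -> pd.DataFrame:
    """Centers of an equal-area coarse grid covering the window.

    Columns have constant longitude width; rows have constant width in
    sin(latitude), so every cell spans the same spherical area
    (~``coarse_cell_km``^2).
    """
    dlam_deg = coarse_cell_km / KM_PER_DEG
    n_cols = max(1, int(round((grid.lon_max - grid.lon_min) / dlam_deg)))
    dlam_deg = (grid.lon_max - grid.lon_min) / n_cols
    dlam_rad = np.radians(dlam_deg)
    dsin = coarse_cell_km**2 / (EARTH_RADIUS_KM**2 * dlam_rad)
    s0, s1 = np.sin(np.radians(grid.lat_min)), np.sin(np.radians(grid.lat_max))
    n_rows = max(1, int(round((s1 - s0) / dsin)))
    sin_edges = np.linspace(s0, s1, n_rows + 1)
    lat_centers = np.degrees(np.arcsin(0.5 * (sin_edges[:-1] + sin_edges[1:])))
    lon_centers = grid.lon_min + (np.arange(n_cols) + 0.5) * dlam_deg
    lon, lat = np.meshgrid(lon_centers, lat_centers)
    return pd.DataFrame(
        {
            "site_id": [f"site{i:05d}" for i in range(lon.size)],
            "lon": lon.ravel(),
            "lat": lat.ravel(),
        }
    )


def build_community_matrix(
    binaries: dict[str, BinaryDistribution],
    coarse_cell_km: float = 100.0,
    land_mask: np.ndarray | None = None,
) -> CommunityMatrix:
    """Sample binary maps at equal-area coarse-cell centers.

    A site's incidence for a species is the value of the species' binary map
    at the predictor cell containing the coarse-cell center. Sites whose
    center falls on a masked (nodata) cell are dropped, as are sites with no
    species; all-zero species columns are retained.
    """
    if not binaries:
        raise ValueError("no binary maps supplied")
    species = sorted(binaries)
    grid = binaries[species[0]].grid
    for s in species:
        if binaries[s].grid != grid:
            raise ValueError("binary maps on different grids")
    sites = equal_area_sites(grid, coarse_cell_km)
    row, col = grid.cell_of(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    ok = (row >= 0) & (col >= 0)
    if land_mask is not None:
        ok2 = ok.copy()
        ok2[ok] = np.asarray(land_mask, bool)[row[ok], col[ok]]
        ok = ok2
    sites, row, col = sites[ok].reset_index(drop=True), row[ok], col[ok]
    inc = np.column_stack([binaries[s].suitable[row, col] for s in species]).astype(int)
    nonzero = inc.sum(axis=1) > 0
    sites = sites[nonzero].reset_index(drop=True)
    inc = inc[nonzero]
    if len(sites) == 0:
        raise ValueError("no coarse site holds any species")
    return CommunityMatrix(sites=sites, incidence=inc, species=species)


def sorensen_distances(cm: CommunityMatrix | np.ndarray) -> np.ndarray:
    """Site x site Sorensen distance matrix, d = 1 - 2|A&B|/(|A|+|B|)."""
    inc = cm.incidence if isinstance(cm, CommunityMatrix) else np.asarray(cm)
    if inc.shape[0] < 2:
        raise ValueError("need at least two sites")
    d = squareform(pdist(inc.astype(bool), metric="dice"))
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# ordination results

@dataclass
class OrdinationResult:
    kind: str  # "NMDS" or "evoPCA"
    scores: np.ndarray  # (n_sites, n_axes)
    site_ids: list[str] = field(default_factory=list)
    stress: float | None = None
    variance_fractions: np.ndarray | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# NMDS: nonmetric SMACOF with isotonic (PAV) regression, Kruskal stress-1

def _config_distances(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(X))


def _disparities(dhat_flat: np.ndarray, order: np.ndarray, iso: IsotonicRegression) -> np.ndarray:
    """Monotone (isotonic) regression of configuration distances on the
    observed-dissimilarity rank order; primary tie treatment."""
    fitted = np.empty_like(dhat_flat)
    fitted[order] = iso.fit_transform(np.arange(len(order)), dhat_flat[order])
    return fitted


def stress1(X: np.ndarray, dissim: np.ndarray) -> float:
    """Kruskal stress-1 of configuration X against observed dissimilarities."""
    dhat = pdist(X)
    dobs = squareform(dissim, checks=False)
    order = np.lexsort((dhat, dobs))
    iso = IsotonicRegression()
    dstar = _disparities(dhat, order, iso)
    denom = (dhat**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - dstar) ** 2).sum() / denom))


def _classical_mds(dissim: np.ndarray, n_axes: int) -> np.ndarray:
    n = dissim.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dissim**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_axes]
    w = np.clip(w[idx], 0, None)
    return V[:, idx] * np.sqrt(w)


def nmds(
    dissim: np.ndarray,
    n_axes: int = 3,
    seed: int = 0,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    site_ids: list[str] | None = None,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Majorization (SMACOF) alternated with isotonic regression of the
    configuration distances on the observed rank order. One start is the
    classical metric-scaling solution, the rest are random; the best final
    configuration is kept, so the result never has higher stress than the
    metric start. Axes are centered and rotated to principal axes.
    """
    dissim = np.asarray(dissim, dtype=float)
    n = dissim.shape[0]
    if dissim.shape != (n, n) or n < 3:
        raise ValueError("need a square dissimilarity matrix over >= 3 sites")
    rng = np.random.default_rng(seed)
    dobs = squareform(dissim, checks=False)
    iso = IsotonicRegression()

    def run(X0: np.ndarray) -> tuple[np.ndarray, float, bool]:
        X = X0.copy()
        best_X, best_s = X.copy(), stress1(X, dissim)
        prev = best_s
        converged = False
        for _ in range(max_iter):
            dhat = pdist(X)
            ordr = np.lexsort((dhat, dobs))
            dstar = _disparities(dhat, ordr, iso)
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dhat > 0, dstar / dhat, 0.0)
            Bm = -squareform(ratio)
            np.fill_diagonal(Bm, -Bm.sum(axis=1))
            X = Bm @ X / n
            s = stress1(X, dissim)
            if s < best_s:
                best_X, best_s = X.copy(), s
            if abs(prev - s) < tol:
                converged = True
                break
            prev = s
        return best_X, best_s, converged

    starts = [_classical_mds(dissim, n_axes)]
    scale = np.mean(dobs) if np.mean(dobs) > 0 else 1.0
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.normal(scale=scale, size=(n, n_axes)))

    best_X, best_s, any_conv = None, np.inf, False
    metric_start_stress = stress1(starts[0], dissim)
    for X0 in starts:
        X, s, conv = run(X0)
        any_conv = any_conv or conv
        if s < best_s:
            best_X, best_s = X, s
    assert best_X is not None
    if best_s > metric_start_stress + 1e-12:  # optimizer never worsens its start
        best_X, best_s = starts[0], metric_start_stress
    if not any_conv:
        warnings.warn("NMDS did not converge in any start; returning best found", stacklevel=2)
    # center and rotate to principal axes (distance-preserving)
    best_X = best_X - best_X.mean(axis=0)
    _, _, Vt = np.linalg.svd(best_X, full_matrices=False)
    best_X = best_X @ Vt.T
    return OrdinationResult(
        kind="NMDS",
        scores=best_X,
        site_ids=list(site_ids) if site_ids is not None else [],
        stress=float(stress1(best_X, dissim)),
        converged=any_conv,
    )


# ---------------------------------------------------------------------------
# evoPCA (Hellinger variant)

def _branch_tip_matrix(tree: dendropy.Tree, species: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(tips x branches indicator, branch lengths) over all non-root edges."""
    tip_index = {s: i for i, s in enumerate(species)}
    missing = [s for s in species if tree.taxon_namespace.get_taxon(s) is None]
    if missing:
        raise KeyError(f"species missing from phylogeny: {', '.join(missing)}")
    cols, lens = [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.edge.length is None:
            continue
        col = np.zeros(len(species))
        for leaf in node.leaf_iter():
            i = tip_index.get(leaf.taxon.label)
            if i is not None:
                col[i] = 1.0
        if col.sum() == 0:
            continue
        cols.append(col)
        lens.append(float(node.edge.length))
    return np.column_stack(cols), np.asarray(lens)


def evo_pca_hellinger(
    cm: CommunityMatrix,
    tree: dendropy.Tree,
    n_axes: int = 3,
) -> OrdinationResult:
    """Phylogenetic ordination: Hellinger PCA of the branch-expanded matrix.

    Site abundance on a branch is the summed incidence of the tips descending
    from it. Each entry is transformed to
    ``sqrt(l_b * x_sb / sum_b'(l_b' * x_sb'))`` (branch-length-weighted
    Hellinger transform), so for a star tree with equal branch lengths the
    ordination reduces exactly to a plain Hellinger PCA of the species
    matrix. Scores are the first ``n_axes`` principal components; variance
    fractions are their shares of total variance.
    """
    T, lens = _branch_tip_matrix(tree, cm.species)
    B = cm.incidence @ T  # sites x branches
    W = B @ lens  # branch-length-weighted site totals
    if np.any(W <= 0):
        raise ValueError("a site has zero branch-length-weighted total")
    Y = np.sqrt(B * lens[None, :] / W[:, None])
    Yc = Y - Y.mean(axis=0)
    U, Sv, _ = np.linalg.svd(Yc, full_matrices=False)
    total = (Sv**2).sum()
    n_axes = min(n_axes, len(Sv))
    scores = U[:, :n_axes] * Sv[:n_axes]
    frac = (Sv[:n_axes] ** 2) / total if total > 0 else np.zeros(n_axes)
    return OrdinationResult(
        kind="evoPCA",
        scores=scores,
        site_ids=list(cm.sites["site_id"]),
        variance_fractions=frac,
    )


# ---------------------------------------------------------------------------
# post-processing

def rgb_map(scores: np.ndarray, p_lo: float = 10.0, p_hi: float = 90.0) -> np.ndarray:
    """Rescale each of 3 axes to [0, 1] between its p_lo/p_hi percentiles."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] != 3:
        raise ValueError("rgb_map needs exactly 3 axes")
    out = np.empty_like(scores)
    for j in range(3):
        lo, hi = np.percentile(scores[:, j], [p_lo, p_hi])
        if hi <= lo:
            warnings.warn(f"axis {j} is constant; mapped to mid-channel", stacklevel=2)
            out[:, j] = 0.5
        else:
            out[:, j] = np.clip((scores[:, j] - lo) / (hi - lo), 0.0, 1.0)
    return out


def iqr_outlier_filter(scores: np.ndarray) -> np.ndarray:
    """Boolean keep-mask: a site stays iff every axis value lies inside
    [Q1 - IQR, Q3 + IQR]. Single pass; quartiles are not recomputed."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < 4:
        raise ValueError("need at least 4 sites")
    q1 = np.percentile(scores, 25, axis=0)
    q3 = np.percentile(scores, 75, axis=0)
    iqr = q3 - q1
    keep = np.all((scores >= q1 - iqr) & (scores <= q3 + iqr), axis=1)
    return keep


def cluster_and_select_k(
    scores: np.ndarray,
    k_range: range | list[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, np.ndarray, dict[int, float]]:
    """K-means over the joint axes; k chosen by highest mean silhouette.

    Ties resolve to the smaller k. Returns (best_k, labels, silhouettes).
    """
    scores = np.asarray(scores, dtype=float)
    sils: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if not 2 <= k <= len(scores) - 1:
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(scores)
        sils[k] = float(silhouette_score(scores, lab))
        labels_by_k[k] = lab
    if not sils:
        raise ValueError("k_range contains no feasible k")
    best_k = min(sils, key=lambda k: (-sils[k], k))
    return best_k, labels_by_k[best_k], sils


def _adjusted_r2(Y: np.ndarray, Xp: np.ndarray) -> float:
    """Adjusted redundancy R^2 of multivariate Y on standardized predictors."""
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    Xc = Xp - Xp.mean(axis=0)
    beta, _, rank, _ = np.linalg.lstsq(Xc, Yc, rcond=None)
    resid = Yc - Xc @ beta
    sst = (Yc**2).sum()
    if sst == 0:
        return 0.0
    r2 = 1.0 - (resid**2).sum() / sst
    p = rank
    if n - p - 1 <= 0:
        return float(r2)
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def rda_and_varpart(scores: np.ndarray, env_at_sites: pd.DataFrame) -> dict:
    """Redundancy analysis of ordination axes on the nine predictors, with
    variation partitioning into climate and soil blocks.

    Returns adjusted R^2 for the full model and the standard partial-R^2
    decomposition: climate_only, soil_only, shared (shared may go slightly
    negative after adjustment; it is reported as computed).
    """
    Y = np.asarray(scores, dtype=float)
    clim = [v for v in CLIMATE_VARS if v in env_at_sites.columns]
    soil = [v for v in SOIL_VARS if v in env_at_sites.columns]
    allv = clim + soil

    def std(cols: list[str]) -> np.ndarray:
        X = env_at_sites[cols].to_numpy(dtype=float)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn("dropping constant predictor column(s)", stacklevel=2)
        X = X[:, keep]
        return (X - X.mean(axis=0)) / X.std(axis=0)

    r2_all = _adjusted_r2(Y, std(allv))
    r2_clim = _adjusted_r2(Y, std(clim)) if clim else 0.0
    r2_soil = _adjusted_r2(Y, std(soil)) if soil else 0.0
    return {
        "total_R2_adj": r2_all,
        "climate_only": r2_all - r2_soil,
        "soil_only": r2_all - r2_clim,
        "shared": r2_clim + r2_soil - r2_all,
    }


def env_pca(env_at_sites: pd.DataFrame, n_axes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA of standardized environmental variables at the sites.

    Returns (site scores on the first ``n_axes`` components, explained
    variance ratios).
    """
    X = env_at_sites.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 sites")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=min(n_axes, Xs.shape[1]))
    scores = pca.fit_transform(Xs)
    return scores, pca.explained_variance_ratio_
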