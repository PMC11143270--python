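"""Ecoregion-level response of species distributions to climate change.

Current and future binary maps for each species are compared within each
forest ecoregion: fractions of species lost and gained, median shifts in
latitude and elevation among persisting species, and the change in
taxonomic (NMDS) and phylogenetic (evoPCA) composition measured as the
Euclidean distance between an ecoregion's current and future rows in the
scaled 3-axis ordination space. Ecoregion metrics aggregate to biome-level
boxplot statistics, and a one-way MANOVA (Pillai's trace) tests whether
biomes diverge in their multivariate response.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .ordination import CommunityMatrix, evo_pca_hellinger, nmds, sorensen_distances
from .sdm import BinaryDistribution
from .worldgen import EnvStack, RegionSet

RESPONSE_METRICS = [
    "frac_lost",
    "frac_gained",
    "median_abs_lat_shift",
    "median_elev_shift",
    "d_tax",
    "d_phy",
]


def ecoregion_species_sets(
    binaries_current: dict[str, BinaryDistribution],
    binaries_future: dict[str, BinaryDistribution],
    regions: RegionSet,
) -> dict[str, tuple[set[str], set[str]]]:
    """Per-ecoregion sets of species with >= 1 suitable cell center inside.

    Membership uses the per-cell ecoregion labels (cell centers; a center on
    a shared boundary belongs to exactly one ecoregion, treated as inside).
    """
    species = sorted(binaries_current)
    if sorted(binaries_future) != species:
        raise ValueError("current and future scenarios cover different species")
    out: dict[str, tuple[set[str], set[str]]] = {}
    for i, (eid, _, _) in enumerate(regions.ecoregions):
        cells = regions.ecoregion_idx == i
        s_now = {s for s in species if (binaries_current[s].suitable & cells).any()}
        s_fut = {s for s in species if (binaries_future[s].suitable & cells).any()}
        out[eid] = (s_now, s_fut)
    return out


def gain_loss(s_now: set[str], s_fut: set[str]) -> tuple[float, float]:
    """(fraction lost, fraction gained) relative to the current species set."""
    if not s_now:
        raise ValueError("current species set is empty; fractions undefined")
    lost = len(s_now - s_fut) / len(s_now)
    gained = len(s_fut - s_now) / len(s_now)
    return lost, gained


def species_medians(binary: BinaryDistribution, elevation: np.ndarray) -> tuple[float, float]:
    """(median latitude, median elevation) over a species' suitable cells."""
    rr, cc = np.nonzero(binary.suitable)
    if len(rr) == 0:
        return np.nan, np.nan
    lat = binary.grid.lat_centers()[rr]
    return float(np.median(lat)), float(np.median(elevation[rr, cc]))


def median_shifts(
    binaries_current: dict[str, BinaryDistribution],
    binaries_future: dict[str, BinaryDistribution],
    elevation: np.ndarray,
    regions: RegionSet,
    sets: dict[str, tuple[set[str], set[str]]] | None = None,
) -> pd.DataFrame:
    """Per-ecoregion median |latitude shift| and (signed) elevation shift.

    Each species' shift is the difference of its whole-range medians between
    future and current distributions; the ecoregion statistic is the median
    over species present in the ecoregion under both climates.
    """
    if sets is None:
        sets = ecoregion_species_sets(binaries_current, binaries_future, regions)
    shifts = {}
    for s in binaries_current:
        lat0, el0 = species_medians(binaries_current[s], elevation)
        lat1, el1 = species_medians(binaries_future[s], elevation)
        shifts[s] = (lat1 - lat0, el1 - el0)
    rows = []
    for eid, (s_now, s_fut) in sets.items():
        both = sorted(s_now & s_fut)
        if not both:
            rows.append({"ecoregion_id": eid, "median_abs_lat_shift": np.nan,
                         "median_elev_shift": np.nan, "n_persisting": 0})
            continue
        dlat = [abs(shifts[s][0]) for s in both if np.isfinite(shifts[s][0])]
        delev = [shifts[s][1] for s in both if np.isfinite(shifts[s][1])]
        rows.append(
            {
                "ecoregion_id": eid,
                "median_abs_lat_shift": float(np.median(dlat)) if dlat else np.nan,
                "median_elev_shift": float(np.median(delev)) if delev else np.nan,
                "n_persisting": len(both),
            }
        )
    return pd.DataFrame(rows)


def ecoregion_composition_change(
    binaries_current: dict[str, BinaryDistribution],
    binaries_future: dict[str, BinaryDistribution],
    regions: RegionSet,
    phylo: dendropy.Tree,
    seed: int = 0,
    n_starts: int = 8,
    sets: dict[str, tuple[set[str], set[str]]] | None = None,
) -> pd.DataFrame:
    """Taxonomic and phylogenetic composition change per ecoregion.

    Builds a (2 x n_ecoregions) x species incidence matrix with one current
    and one future row per ecoregion, ordinates it once with NMDS (Sorensen,
    3 axes) and once with the phylogenetic Hellinger PCA, scales every axis
    to zero mean and unit variance across all rows, and reports the
    Euclidean distance between each ecoregion's current and future rows.
    Ecoregions with an empty row are dropped with a note.
    """
    species = sorted(binaries_current)
    if sets is None:
        sets = ecoregion_species_sets(binaries_current, binaries_future, regions)
    eids, rows = [], []
    for eid, (s_now, s_fut) in sets.items():
        if not s_now or not s_fut:
            warnings.warn(f"ecoregion {eid} empty in one scenario; dropped from ordination",
                          stacklevel=2)
            continue
        eids.append(eid)
        rows.append([int(s in s_now) for s in species])
        rows.append([int(s in s_fut) for s in species])
    if len(eids) < 3:
        raise ValueError("need at least 3 ecoregions with non-empty sets")
    inc = np.asarray(rows)
    site_ids = [f"{eid}:{w}" for eid in eids for w in ("now", "fut")]
    cm = CommunityMatrix(
        sites=pd.DataFrame({"site_id": site_ids, "lon": 0.0, "lat": 0.0}),
        incidence=inc,
        species=species,
    )

    def scaled_scores(scores: np.ndarray) -> np.ndarray:
        # axes with (numerically) zero variance are dropped from the distance
        # rather than scaled up from float noise
        sd = scores.std(axis=0)
        floor = 1e-9 * max(float(np.abs(scores).max()), 1.0)
        out = np.zeros_like(scores)
        live = sd > floor
        out[:, live] = (scores[:, live] - scores[:, live].mean(axis=0)) / sd[live]
        return out

    # identical communities must land on identical ordination points, so the
    # NMDS runs on the unique incidence rows (primary tie handling would
    # otherwise be free to embed zero-dissimilarity pairs apart)
    uniq, inv = np.unique(inc, axis=0, return_inverse=True)
    if len(uniq) == 1:
        tax_scores = np.zeros((len(inc), 3))
    elif len(uniq) == 2:
        d = sorensen_distances(uniq)[0, 1]
        u = np.zeros((2, 3))
        u[1, 0] = d
        tax_scores = u[inv]
    else:
        u = nmds(sorensen_distances(uniq), seed=seed, n_starts=n_starts).scores
        tax_scores = u[inv]
    d_tax = _row_pair_distances(scaled_scores(tax_scores))
    d_phy = _row_pair_distances(scaled_scores(evo_pca_hellinger(cm, phylo).scores))
    return pd.DataFrame({"ecoregion_id": eids, "d_tax": d_tax, "d_phy": d_phy})


def _row_pair_distances(scores: np.ndarray) -> np.ndarray:
    now = scores[0::2]
    fut = scores[1::2]
    return np.sqrt(((now - fut) ** 2).sum(axis=1))


def ecoregion_responses(
    binaries_current: dict[str, BinaryDistribution],
    binaries_future: dict[str, BinaryDistribution],
    env: EnvStack,
    regions: RegionSet,
    phylo: dendropy.Tree,
    seed: int = 0,
    n_starts: int = 8,
) -> pd.DataFrame:
    """All six response metrics per forest ecoregion, with biome labels."""
    sets = ecoregion_species_sets(binaries_current, binaries_future, regions)
    biome = regions.biome_of()
    rows = []
    for eid, (s_now, s_fut) in sets.items():
        if not s_now:
            continue  # fractions undefined; ecoregion dropped with note downstream
        lost, gained = gain_loss(s_now, s_fut)
        rows.append({"ecoregion_id": eid, "biome": biome[eid],
                     "frac_lost": lost, "frac_gained": gained})
    df = pd.DataFrame(rows)
    shifts = median_shifts(binaries_current, binaries_future, env.elevation, regions, sets)
    comp = ecoregion_composition_change(
        binaries_current, binaries_future, regions, phylo, seed=seed, n_starts=n_starts, sets=sets
    )
    df = df.merge(shifts, on="ecoregion_id", how="left")
    df = df.merge(comp, on="ecoregion_id", how="left")
    return df


def biome_summary(responses: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Boxplot statistics and normal-theory CI of the mean per biome and metric.

    Quartiles use linear interpolation between order statistics (type 7);
    whiskers follow the boxplot convention (most extreme point within
    1.5 IQR of the box). The 95% CI of the mean uses the t distribution and
    is undefined (NaN) for single-ecoregion biomes.
    """
    if metrics is None:
        metrics = [m for m in RESPONSE_METRICS if m in responses.columns]
    rows = []
    for biome, grp in responses.groupby("biome"):
        for metric in metrics:
            x = grp[metric].dropna().to_numpy(dtype=float)
            if len(x) == 0:
                continue
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            iqr = q3 - q1
            in_lo = x[x >= q1 - 1.5 * iqr]
            in_hi = x[x <= q3 + 1.5 * iqr]
            mean = x.mean()
            if len(x) > 1:
                half = stats.t.ppf(0.975, len(x) - 1) * x.std(ddof=1) / np.sqrt(len(x))
                ci = (mean - half, mean + half)
            else:
                ci = (np.nan, np.nan)
            rows.append(
                {
                    "biome": biome,
                    "metric": metric,
                    "n_ecoregions": len(x),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_lo": float(in_lo.min()) if len(in_lo) else np.nan,
                    "whisker_hi": float(in_hi.max()) if len(in_hi) else np.nan,
                    "mean": mean,
                    "ci_lo": ci[0],
                    "ci_hi": ci[1],
                }
            )
    return pd.DataFrame(rows)


def pillai_test(responses: pd.DataFrame, metrics: list[str] | None = None) -> dict:
    """One-way MANOVA of the response metrics on the biome factor.

    Pillai's trace V = sum(lambda_i / (1 + lambda_i)) over the eigenvalues of
    H E^-1 (between / within SSCP matrices), with the standard F
    approximation: s = min(p, g-1), m = (|p-g+1|-1)/2, n = (N-g-p-1)/2,
    F = [(2n+s+1)/(2m+s+1)] * V/(s-V) on (s(2m+s+1), s(2n+s+1)) df.
    """
    if metrics is None:
        metrics = [m for m in RESPONSE_METRICS if m in responses.columns]
    if not metrics:
        raise ValueError("no response metrics to test")
    df = responses.dropna(subset=metrics)
    # metrics without variation carry no information and make E singular
    live = [m for m in metrics if df[m].var() > 1e-18]
    if not live:
        return {"pillai_trace": 0.0, "F_approx": 0.0, "p": 1.0,
                "df1": np.nan, "df2": np.nan, "note": "no variation in any metric"}
    if len(live) < len(metrics):
        warnings.warn(
            f"dropping zero-variance metric(s): {sorted(set(metrics) - set(live))}",
            stacklevel=2,
        )
    metrics = live
    groups = df.groupby("biome")
    g = groups.ngroups
    if g < 2 or any(len(grp) < 2 for _, grp in groups):
        raise ValueError("need >= 2 biomes each with >= 2 ecoregions")
    Y = df[metrics].to_numpy(dtype=float)
    p = Y.shape[1]
    N = Y.shape[0]
    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for _, grp in groups:
        Yg = grp[metrics].to_numpy(dtype=float)
        mg = Yg.mean(axis=0)
        d = (mg - grand)[:, None]
        H += len(Yg) * (d @ d.T)
        R = Yg - mg
        E += R.T @ R
    try:
        M = np.linalg.solve(E, H)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "within-group covariance is singular; consider dropping a metric"
        ) from err
    lam = np.linalg.eigvals(M).real
    lam = np.clip(lam, 0, None)
    V = float((lam / (1 + lam)).sum())
    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2
    n = (N - g - p - 1) / 2
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n + s + 1)
    if df2 <= 0 or V >= s:
        return {"pillai_trace": V, "F_approx": np.inf, "p": 0.0, "df1": df1, "df2": df2}
    F = (df2 / df1) * V / (s - V)
    pval = float(stats.f.sf(F, df1, df2))
    return {"pillai_trace": V, "F_approx": float(F), "p": pval, "df1": df1, "df2": df2}
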