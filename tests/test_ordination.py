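"""Ordinations: community matrix, Sorensen, NMDS (with an independent PAV
stress oracle), Hellinger evoPCA, RGB scaling, outlier filter, clustering,
RDA/variation partitioning, environmental PCA."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.linalg import subspace_angles
from scipy.spatial.distance import pdist, squareform

from treescape import GridSpec
from treescape.ordination import (
    CommunityMatrix,
    build_community_matrix,
    cluster_and_select_k,
    env_pca,
    equal_area_sites,
    evo_pca_hellinger,
    iqr_outlier_filter,
    nmds,
    rda_and_varpart,
    rgb_map,
    sorensen_distances,
    stress1,
)
from treescape.sdm import BinaryDistribution
from treescape.worldgen import CLIMATE_VARS, SOIL_VARS

GRID = GridSpec(lon_min=0.0, lon_max=20.0, lat_min=0.0, lat_max=20.0, resolution=1.0)


def _binary(values):
    return BinaryDistribution(grid=GRID, values=values.astype(bool),
                              valid=np.ones(GRID.shape, bool))


def _star_cm(rng, n_sites=20, n_species=8):
    inc = (rng.random((n_sites, n_species)) < 0.5).astype(int)
    inc[inc.sum(axis=1) == 0, 0] = 1
    species = [f"s{i}" for i in range(n_species)]
    sites = pd.DataFrame({
        "site_id": [f"site{i}" for i in range(n_sites)],
        "lon": np.zeros(n_sites),
        "lat": np.zeros(n_sites),
    })
    return CommunityMatrix(sites=sites, incidence=inc, species=species)


def _star_tree(species, length=1.0):
    newick = "(" + ",".join(f"{s}:{length}" for s in species) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


class TestCommunityMatrix:
    def test_equal_area_rows_have_equal_area(self):
        sites = equal_area_sites(GRID, coarse_cell_km=300.0)
        # by construction every coarse cell spans the same sin(lat) width
        lats = np.unique(sites["lat"])
        sins = np.sin(np.radians(lats))
        steps = np.diff(np.sort(sins))
        assert np.allclose(steps, steps[0], rtol=1e-6)

    def test_full_coverage_species_gives_all_ones_column(self):
        b = _binary(np.ones(GRID.shape))
        cm = build_community_matrix({"sp": b}, coarse_cell_km=300.0)
        assert (cm.incidence == 1).all()

    def test_absent_species_column_retained_sites_dropped_by_row(self):
        full = _binary(np.ones(GRID.shape))
        empty = _binary(np.zeros(GRID.shape))
        cm = build_community_matrix({"a": full, "b": empty}, coarse_cell_km=300.0)
        assert cm.incidence[:, cm.species.index("b")].sum() == 0
        assert (cm.incidence.sum(axis=1) > 0).all()

    def test_masked_center_drops_site(self):
        b = _binary(np.ones(GRID.shape))
        land = np.ones(GRID.shape, bool)
        sites = equal_area_sites(GRID, 300.0)
        r0, c0 = GRID.cell_of(sites.loc[0, "lon"], sites.loc[0, "lat"])
        land[r0, c0] = False
        cm = build_community_matrix({"sp": b}, 300.0, land_mask=land)
        all_sites = len(sites)
        assert cm.n_sites == all_sites - 1

    def test_no_nonempty_site_rejected(self):
        empty = _binary(np.zeros(GRID.shape))
        with pytest.raises(ValueError):
            build_community_matrix({"a": empty}, 300.0)


class TestSorensen:
    def test_worked_values(self):
        inc = np.array([
            [1, 1, 0],  # {s1, s2}
            [0, 1, 1],  # {s2, s3}
            [1, 1, 0],  # duplicate of site 0
            [0, 0, 1],  # disjoint from site 0
        ])
        d = sorensen_distances(inc)
        assert d[0, 1] == pytest.approx(0.5)
        assert d[0, 2] == pytest.approx(0.0)
        assert d[0, 3] == pytest.approx(1.0)

    def test_matches_formula_on_random_incidence(self, rng):
        inc = (rng.random((15, 10)) < 0.4).astype(int)
        inc[inc.sum(axis=1) == 0, 0] = 1
        d = sorensen_distances(inc)
        for i in range(15):
            for j in range(15):
                a = np.logical_and(inc[i], inc[j]).sum()
                expected = 1 - 2 * a / (inc[i].sum() + inc[j].sum())
                assert d[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()


def _pav_stress1(X, dissim):
    """Independent Kruskal stress-1: hand-written pool-adjacent-violators."""
    dhat = pdist(X)
    dobs = squareform(dissim, checks=False)
    order = np.lexsort((dhat, dobs))
    y = dhat[order]
    # PAV: non-decreasing fit minimizing squared error
    blocks = [[v, 1.0] for v in y]
    merged = []
    for val, w in blocks:
        merged.append([val, w])
        while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
            v2, w2 = merged.pop()
            v1, w1 = merged.pop()
            merged.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
    fit = np.concatenate([[v] * int(w) for v, w in merged])
    dstar = np.empty_like(dhat)
    dstar[order] = fit
    return np.sqrt(((dhat - dstar) ** 2).sum() / (dhat**2).sum())


class TestNMDS:
    def test_perfect_embedding_of_euclidean_dissimilarities(self, rng):
        X = rng.normal(size=(40, 3))
        D = squareform(pdist(X))
        res = nmds(D, seed=0, n_starts=8)
        assert res.stress < 1e-3

    def test_stress_matches_independent_pav_oracle(self, rng):
        D = squareform(np.abs(rng.normal(size=30 * 29 // 2)))
        np.fill_diagonal(D, 0)
        D = (D + D.T) / 2
        res = nmds(D, seed=1, n_starts=4, max_iter=100)
        assert res.stress == pytest.approx(_pav_stress1(res.scores, D), abs=1e-8)

    def test_never_worse_than_metric_start(self, rng):
        from treescape.ordination import _classical_mds

        D = squareform(np.abs(rng.normal(size=25 * 24 // 2)))
        np.fill_diagonal(D, 0)
        D = (D + D.T) / 2
        start_stress = stress1(_classical_mds(D, 3), D)
        res = nmds(D, seed=2, n_starts=4, max_iter=100)
        assert res.stress <= start_stress + 1e-12

    def test_stress_invariant_to_rotation_translation(self, rng):
        X = rng.normal(size=(20, 3))
        D = squareform(pdist(X)) + 0.05 * squareform(np.abs(rng.normal(size=190)))
        np.fill_diagonal(D, 0)
        D = (D + D.T) / 2
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert stress1(X, D) == pytest.approx(stress1(X @ Q + 5.0, D), abs=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((2, 2)))


class TestEvoPCA:
    def test_star_tree_reduces_to_plain_hellinger_pca(self, rng):
        cm = _star_cm(rng)
        res = evo_pca_hellinger(cm, _star_tree(cm.species))
        H = np.sqrt(cm.incidence / cm.incidence.sum(axis=1, keepdims=True))
        Hc = H - H.mean(axis=0)
        U, S, _ = np.linalg.svd(Hc, full_matrices=False)
        plain = U[:, :3] * S[:3]
        assert subspace_angles(res.scores, plain).max() < 1e-6

    def test_identical_sites_get_identical_scores(self, rng):
        cm = _star_cm(rng)
        cm.incidence[1] = cm.incidence[0]
        tree = _star_tree(cm.species)
        res = evo_pca_hellinger(cm, tree)
        assert np.allclose(res.scores[0], res.scores[1], atol=1e-12)

    def test_variance_fractions_monotone_and_bounded(self, rng):
        cm = _star_cm(rng)
        res = evo_pca_hellinger(cm, _star_tree(cm.species))
        vf = res.variance_fractions
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() <= 1.0 + 1e-12

    def test_missing_species_named_in_error(self, rng):
        cm = _star_cm(rng)
        tree = _star_tree(cm.species[:-1])
        with pytest.raises(KeyError, match=cm.species[-1]):
            evo_pca_hellinger(cm, tree)


class TestRGBAndOutliers:
    def test_percentile_endpoints_and_clipping(self, rng):
        scores = np.column_stack([np.arange(100.0), rng.normal(size=100), rng.normal(size=100)])
        rgb = rgb_map(scores)
        lo, hi = np.percentile(scores[:, 0], [10, 90])
        i_lo = int(np.where(scores[:, 0] == np.floor(lo))[0][0]) if lo == int(lo) else None
        assert rgb[:, 0].min() == 0.0 and rgb[:, 0].max() == 1.0
        above = scores[:, 0] >= hi
        assert (rgb[above, 0] == 1.0).all()
        below = scores[:, 0] <= lo
        assert (rgb[below, 0] == 0.0).all()

    def test_constant_axis_mid_channel_with_warning(self, rng):
        scores = np.column_stack([np.ones(30), rng.normal(size=30), rng.normal(size=30)])
        with pytest.warns(UserWarning):
            rgb = rgb_map(scores)
        assert (rgb[:, 0] == 0.5).all()

    def test_monotone_transform_preserves_channel_order(self, rng):
        scores = np.column_stack([rng.normal(size=50), rng.normal(size=50), rng.normal(size=50)])
        rgb1 = rgb_map(scores)
        scores2 = scores.copy()
        scores2[:, 0] = np.exp(scores2[:, 0])
        rgb2 = rgb_map(scores2)
        interior = (rgb1[:, 0] > 0) & (rgb1[:, 0] < 1) & (rgb2[:, 0] > 0) & (rgb2[:, 0] < 1)
        order1 = np.argsort(rgb1[interior, 0], kind="stable")
        order2 = np.argsort(rgb2[interior, 0], kind="stable")
        assert np.array_equal(order1, order2)

    def test_iqr_outlier_removed(self):
        axis = np.zeros(20)
        axis[-1] = 100.0
        scores = np.column_stack([axis, np.zeros(20), np.zeros(20)])
        keep = iqr_outlier_filter(scores)
        assert not keep[-1]
        assert keep[:-1].all()

    def test_constant_scores_nothing_removed(self):
        scores = np.ones((10, 3))
        assert iqr_outlier_filter(scores).all()

    def test_single_pass_not_idempotent_in_general(self, rng):
        # quartiles are not recomputed: re-running on the filtered output may
        # remove more points
        axis = np.concatenate([np.zeros(12), [5.0, 6.0, 100.0]])
        scores = np.column_stack([axis, np.zeros(15), np.zeros(15)])
        keep1 = iqr_outlier_filter(scores)
        keep2 = iqr_outlier_filter(scores[keep1])
        assert keep1.sum() >= keep2.sum()


class TestClustering:
    def test_two_separated_blobs_selects_k2(self, rng):
        a = rng.normal(size=(40, 3)) + np.array([10, 0, 0])
        b = rng.normal(size=(40, 3)) - np.array([10, 0, 0])
        scores = np.vstack([a, b])
        best_k, labels, sils = cluster_and_select_k(scores, range(2, 7), seed=0)
        assert best_k == 2
        assert sils[2] > 0.7
        assert len(labels) == 80
        assert set(labels) == {0, 1}

    def test_duplicating_points_keeps_silhouette(self, rng):
        a = rng.normal(size=(20, 3)) + np.array([8, 0, 0])
        b = rng.normal(size=(20, 3)) - np.array([8, 0, 0])
        scores = np.vstack([a, b])
        _, _, sils1 = cluster_and_select_k(scores, [2], seed=0)
        _, _, sils2 = cluster_and_select_k(np.vstack([scores, scores]), [2], seed=0)
        # the within-cluster mean divides by |C|-1, so duplication shifts the
        # coefficient by O(1/n); assert near-invariance at that scale
        assert sils2[2] == pytest.approx(sils1[2], abs=0.02)

    def test_infeasible_k_range_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_and_select_k(rng.normal(size=(5, 3)), [10], seed=0)


class TestRdaVarpart:
    def _env(self, rng, n):
        return pd.DataFrame(rng.normal(size=(n, 9)), columns=CLIMATE_VARS + SOIL_VARS)

    def test_exact_linear_scores_r2_one(self, rng):
        X = self._env(rng, 60)
        B = rng.normal(size=(9, 3))
        scores = X.to_numpy() @ B
        out = rda_and_varpart(scores, X)
        assert out["total_R2_adj"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_scores_r2_near_zero(self, rng):
        X = self._env(rng, 2000)
        scores = rng.normal(size=(2000, 3))
        out = rda_and_varpart(scores, X)
        assert abs(out["total_R2_adj"]) < 0.05

    def test_partition_identity(self, rng):
        X = self._env(rng, 200)
        scores = X[CLIMATE_VARS].to_numpy() @ rng.normal(size=(6, 3)) \
            + 0.5 * rng.normal(size=(200, 3))
        out = rda_and_varpart(scores, X)
        total = out["climate_only"] + out["soil_only"] + out["shared"]
        assert total == pytest.approx(out["total_R2_adj"], abs=1e-9)
        assert out["climate_only"] > out["soil_only"]


class TestEnvPCA:
    def test_axis_order_by_variance(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 5)) * [5, 3, 1, 1, 1])
        _, ratio = env_pca(X)
        assert ratio[0] >= ratio[1]

    def test_two_perfectly_correlated_variables(self, rng):
        a = rng.normal(size=80)
        X = pd.DataFrame({"u": a, "v": 2 * a + 1})
        _, ratio = env_pca(X)
        assert ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_invariant_to_variable_permutation(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        s1, _ = env_pca(X)
        s2, _ = env_pca(X[["d", "b", "a", "c"]])
        # same subspace up to sign
        assert subspace_angles(s1, s2).max() < 1e-9
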