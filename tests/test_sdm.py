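"""Ensemble distribution model: training schedule, predictor rule, max-TSS
threshold, prediction/binarization, plot evaluation, IoU."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from treescape import GridSpec
from treescape import sdm
from treescape.sdm import (
    BinaryDistribution,
    TrainingSet,
    evaluate_plots,
    iou,
    max_tss_threshold,
    pseudoabsence_schedule,
    sample_training,
    select_predictors,
    tss_at,
)
from treescape.worldgen import PREDICTORS


class TestPseudoabsenceSchedule:
    @pytest.mark.parametrize("n_obs,expected", [
        (12_000, (10_000, 10_000)),
        (10_000, (10_000, 10_000)),
        (9_999, (9_999, 10_001)),
        (1_818, (1_818, 18_182)),
        (1_817, (1_817, 18_170)),
        (500, (500, 5_000)),
        (499, (499, 5_000)),
        (300, (300, 5_000)),
        (20, (20, 5_000)),
    ])
    def test_schedule_table(self, n_obs, expected):
        assert pseudoabsence_schedule(n_obs) == expected

    def test_ineligible_below_twenty(self):
        with pytest.raises(ValueError):
            pseudoabsence_schedule(19)

    @settings(max_examples=200, deadline=None)
    @given(n_obs=st.integers(20, 50_000))
    def test_total_capped_at_twenty_thousand(self, n_obs):
        n_p, n_pa = pseudoabsence_schedule(n_obs)
        assert n_p + n_pa <= 20_000
        assert n_p <= n_obs
        assert n_pa >= 0


class TestSelectPredictors:
    @pytest.mark.parametrize("n_obs,k", [(20, 2), (25, 2), (29, 2), (30, 3), (89, 8), (90, 9), (500, 9)])
    def test_ten_observations_per_predictor_rule(self, n_obs, k, rng):
        X = pd.DataFrame(rng.normal(size=(60, 9)), columns=PREDICTORS)
        y = (rng.random(60) < 0.5).astype(int)
        y[:2] = [0, 1]  # both classes
        t = TrainingSet(X=X, y=y, presence_cells=np.empty((0, 2)),
                        absence_cells=np.empty((0, 2)), n_obs=n_obs)
        sel = select_predictors(t, n_obs, seed=1)
        assert len(sel) == k
        assert set(sel) <= set(PREDICTORS)

    def test_perfect_separator_ranks_first(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 9)), columns=PREDICTORS)
        y = (rng.random(200) < 0.5).astype(int)
        X["gsl"] = y * 10.0 + rng.normal(scale=0.01, size=200)  # separates classes
        t = TrainingSet(X=X, y=y, presence_cells=np.empty((0, 2)),
                        absence_cells=np.empty((0, 2)), n_obs=30)
        sel = select_predictors(t, 30, seed=1)
        assert sel[0] == "gsl"

    def test_full_set_kept_without_refit(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 9)), columns=PREDICTORS)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        t = TrainingSet(X=X, y=y, presence_cells=np.empty((0, 2)),
                        absence_cells=np.empty((0, 2)), n_obs=90)
        assert select_predictors(t, 90, seed=1) == list(PREDICTORS)


class TestMaxTssThreshold:
    def test_six_point_worked_example(self):
        scores = np.array([0.1, 0.2, 0.4, 0.3, 0.8, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 1])
        thr, tss = max_tss_threshold(scores, labels)
        assert thr == pytest.approx(0.4)
        assert tss == pytest.approx(1.0)

    def test_scores_equal_labels(self):
        labels = np.array([0, 1, 0, 1, 1, 0])
        thr, tss = max_tss_threshold(labels.astype(float), labels)
        assert tss == pytest.approx(1.0)
        assert thr <= 1.0 and thr > 0.0

    def test_random_scores_near_zero_skill(self, rng):
        scores = rng.random(10_000)
        labels = (rng.random(10_000) < 0.5).astype(int)
        _, tss = max_tss_threshold(scores, labels)
        # optimized TSS is biased slightly above 0 on noise; stays small
        assert 0.0 <= tss < 0.08

    def test_smallest_maximizer_returned_on_ties(self):
        scores = np.array([0.2, 0.2, 0.7, 0.7])
        labels = np.array([0, 0, 1, 1])
        thr, tss = max_tss_threshold(scores, labels)
        assert tss == pytest.approx(1.0)
        assert thr == pytest.approx(0.7)  # 0.2 gives sens 1, spec 0; 0.7 is first max

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_bruteforce_grid(self, seed):
        # scores on a 0.01 lattice so the 0.001 reference grid cannot miss a
        # plateau between consecutive unique scores
        r = np.random.default_rng(seed)
        n = 80
        scores = r.integers(0, 101, size=n) / 100.0
        labels = (r.random(n) < 0.4 + 0.2 * scores).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        thr, tss = max_tss_threshold(scores, labels)
        grid = np.arange(0.0, 1.0005, 0.001)
        brute = max(tss_at(scores, labels, t) for t in grid)
        assert tss == pytest.approx(brute, abs=1e-9)


class TestSampleTraining:
    def test_pseudoabsences_inside_range_and_off_presences(self, world, aggregated, fitted):
        sid = fitted["sid"]
        poly = fitted["range"].geometry
        t = sample_training(aggregated.cells[sid], poly, world.env, seed=3)
        from treescape.sdm import range_mask

        inside = range_mask(poly, world.grid, world.env.mask)
        cells = np.vstack([t.presence_cells, t.absence_cells])
        assert inside[cells[:, 0], cells[:, 1]].all()
        pres = {tuple(c) for c in t.presence_cells}
        assert pres.isdisjoint({tuple(c) for c in t.absence_cells})

    def test_fixed_seed_reproducible(self, world, aggregated, fitted):
        sid = fitted["sid"]
        poly = fitted["range"].geometry
        a = sample_training(aggregated.cells[sid], poly, world.env, seed=3)
        b = sample_training(aggregated.cells[sid], poly, world.env, seed=3)
        assert np.array_equal(a.absence_cells, b.absence_cells)
        assert a.X.equals(b.X)

    def test_exhaustion_warns_and_uses_all(self, world, aggregated, fitted):
        sid = fitted["sid"]
        cells = aggregated.cells[sid]
        # the tight bounding box of the presences leaves few free cells
        lon = world.grid.lon_centers()[cells[:, 1]]
        lat = world.grid.lat_centers()[cells[:, 0]]
        tight = box(lon.min() - 0.3, lat.min() - 0.3, lon.max() + 0.3, lat.max() + 0.3)
        with pytest.warns(UserWarning, match="pseudoabsence"):
            t = sample_training(cells, tight, world.env, seed=3)
        assert t.n_pa_training < pseudoabsence_schedule(t.n_obs)[1]


class TestEnsembleAndPrediction:
    def test_ensemble_probability_is_member_mean(self, fitted):
        X = fitted["model"].training.X.head(50)
        res = fitted["results"]
        probs = [m.predict_proba(X[res.predictors])[:, 1] for m in res.members.values()]
        assert np.allclose(res.predict_proba(X), np.mean(probs, axis=0))
        assert (res.predict_proba(X) <= np.max(probs, axis=0) + 1e-12).all()
        assert (res.predict_proba(X) >= np.min(probs, axis=0) - 1e-12).all()

    def test_single_class_training_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 9)), columns=PREDICTORS)
        t = TrainingSet(X=X, y=np.ones(30, int), presence_cells=np.empty((0, 2)),
                        absence_cells=np.empty((0, 2)), n_obs=30)
        model = sdm.SpeciesDistributionModel(t, predictors=list(PREDICTORS))
        with pytest.raises(ValueError):
            model.fit(seed=0)

    def test_linearly_separable_data_perfect_cv_skill(self, rng):
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 9)), columns=PREDICTORS)
        y = (X["mat"] > 0).astype(int).to_numpy()
        X["mat"] = X["mat"] + y * 10.0  # widen the margin
        t = TrainingSet(X=X, y=y, presence_cells=np.empty((0, 2)),
                        absence_cells=np.empty((0, 2)), n_obs=n)
        res = sdm.SpeciesDistributionModel(t, predictors=list(PREDICTORS)).fit(seed=1)
        assert res.cv_tss == pytest.approx(1.0, abs=1e-9)
        assert res.cv_auc == pytest.approx(1.0, abs=1e-9)

    def test_outside_range_is_nodata(self, fitted):
        suit, binary = fitted["suit"], fitted["binary"]
        outside = ~binary.valid
        assert np.isnan(suit.values[outside]).all()
        assert not binary.suitable[outside].any()

    def test_binary_follows_threshold_with_ge_convention(self, fitted):
        res, suit, binary = fitted["results"], fitted["suit"], fitted["binary"]
        v = binary.valid
        assert np.array_equal(binary.values[v], suit.values[v] >= res.threshold)

    def test_zero_delta_scenario_reproduces_current_maps(self, world, fitted):
        env = world.env
        env2 = type(env)(
            grid=env.grid, layers=env.layers, elevation=env.elevation,
            mask=env.mask, future={"null": dict(env.layers)},
        )
        res = fitted["results"]
        s_cur, b_cur = res.predict_map(env2, fitted["range"].geometry, "current")
        s_fut, b_fut = res.predict_map(env2, fitted["range"].geometry, "null")
        assert np.array_equal(b_cur.suitable, b_fut.suitable)
        assert np.allclose(s_cur.values[b_cur.valid], s_fut.values[b_fut.valid])

    def test_missing_scenario_rejected(self, world, fitted):
        with pytest.raises(KeyError):
            fitted["results"].predict_map(world.env, fitted["range"].geometry, "ssp000")

    def test_summary_mentions_key_quantities(self, fitted):
        text = fitted["results"].summary()
        assert "threshold" in text and "TSS" in text and "AUC" in text


GRID4 = GridSpec(lon_min=0, lon_max=4, lat_min=0, lat_max=4, resolution=1.0)


def _binary(cells):
    values = np.zeros(GRID4.shape, dtype=bool)
    for r, c in cells:
        values[r, c] = True
    return BinaryDistribution(grid=GRID4, values=values, valid=np.ones(GRID4.shape, bool))


class TestIoU:
    def test_identical_maps(self):
        a = _binary([(0, 0), (1, 1)])
        assert iou(a, a) == 1.0

    def test_disjoint_maps(self):
        assert iou(_binary([(0, 0)]), _binary([(1, 1)])) == 0.0

    def test_partial_overlap_one_third(self):
        a = _binary([(0, 0), (1, 1)])
        b = _binary([(1, 1), (2, 2)])
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_empty_union_flagged(self):
        with pytest.warns(UserWarning):
            assert iou(_binary([]), _binary([])) == 0.0

    def test_grid_mismatch_rejected(self):
        other = BinaryDistribution(
            grid=GridSpec(lon_min=0, lon_max=8, lat_min=0, lat_max=8, resolution=1.0),
            values=np.zeros((8, 8), bool), valid=np.ones((8, 8), bool),
        )
        with pytest.raises(ValueError):
            iou(_binary([]), other)


class TestEvaluatePlots:
    def _plots(self, rows):
        return pd.DataFrame(rows, columns=["plot_id", "lon", "lat", "species_id", "present"])

    def test_perfect_agreement(self):
        binary = _binary([(0, 0), (0, 1)])
        rows = []
        for c in range(4):
            for r in range(4):
                rows.append((f"p{r}{c}", GRID4.lon_centers()[c], GRID4.lat_centers()[r],
                             "sp", bool(binary.values[r, c])))
        # need >= 5 presences: duplicate suitable-cell plots
        rows += [("px1", GRID4.lon_centers()[0] + 0.1, GRID4.lat_centers()[0], "sp", True),
                 ("px2", GRID4.lon_centers()[1] + 0.1, GRID4.lat_centers()[0], "sp", True),
                 ("px3", GRID4.lon_centers()[0] - 0.1, GRID4.lat_centers()[0], "sp", True)]
        m = evaluate_plots(binary, self._plots(rows), box(0, 0, 4, 4))
        assert m["TSS"] == pytest.approx(1.0)
        assert m["precision"] == 1.0 and m["recall"] == 1.0

    def test_fewer_than_five_inrange_presences_skipped(self):
        binary = _binary([(0, 0)])
        rows = [(f"p{i}", 0.5 + i, 3.5, "sp", True) for i in range(4)]
        assert evaluate_plots(binary, self._plots(rows), box(0, 0, 4, 4)) is None

    def test_confusion_matrix_arithmetic(self):
        # TP=8, FN=2, FP=3, TN=7 -> recall .8, precision 8/11, TSS .5
        # suitable cells: rows 0-1 and the first 3 cells of row 2 (11 cells);
        # plots may share cells (within-cell offsets), only labels matter
        vals = np.zeros(GRID4.shape, bool)
        suitable = [(r, c) for r in range(2) for c in range(4)] + [(2, 0), (2, 1), (2, 2)]
        unsuitable = [(2, 3)] + [(3, c) for c in range(4)]
        for r, c in suitable:
            vals[r, c] = True

        def plot(pid, cell, present, off=0.0):
            r, c = cell
            return (pid, GRID4.lon_centers()[c] + off, GRID4.lat_centers()[r], "sp", present)

        plots = [plot(f"tp{i}", suitable[i], True) for i in range(8)]          # TP
        plots += [plot(f"fn{i}", unsuitable[i], True) for i in range(2)]       # FN
        plots += [plot(f"fp{i}", suitable[8 + i], False) for i in range(3)]    # FP
        plots += [plot(f"tn{i}", unsuitable[i % 5], False, off=0.1 + 0.02 * i)
                  for i in range(7)]                                           # TN
        binary = BinaryDistribution(grid=GRID4, values=vals, valid=np.ones(GRID4.shape, bool))
        m = evaluate_plots(binary, self._plots(plots), box(0, 0, 4, 4))
        assert m["recall"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(8 / 11)
        assert m["TSS"] == pytest.approx(0.8 + 0.7 - 1.0)

    def test_plots_outside_range_excluded(self):
        binary = _binary([(0, 0)])
        rows = [(f"p{i}", 0.5, 3.5, "sp", True) for i in range(6)]
        rows += [(f"q{i}", 10.0, 10.0, "sp", False) for i in range(6)]  # outside
        m = evaluate_plots(binary, self._plots(rows), box(0, 0, 4, 4))
        assert m["n_plots"] == 6
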