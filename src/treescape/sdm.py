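"""Ensemble species distribution model with max-TSS binarization.

For one species, the model is trained on presence cells plus pseudoabsences
sampled uniformly inside the species' geographic range, following a fixed
schedule that caps the training set at 20,000 points:

===================  ==============  =================
n_obs                n_obs,training  n_PA,training
===================  ==============  =================
>= 10,000            10,000          10,000
1818 <= n < 10,000   n_obs           20,000 - n_obs
500 <= n < 1818      n_obs           10 * n_obs
< 500                n_obs           5000
===================  ==============  =================

The ensemble averages two random forests and two gradient-boosted tree
classifiers of differing complexity. The probability-to-binary threshold is
chosen by pooled 3-fold cross-validation, maximizing the true skill
statistic (TSS = sensitivity + specificity - 1); the final ensemble is refit
on the full training set. Predictions are clipped to the range polygon and
the predictor count obeys a 10-observations-per-predictor rule, selecting
the most important predictors from an all-predictor random forest when the
full set of nine cannot be supported.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_auc_score

from .grid import GridSpec
from .worldgen import EnvStack, PREDICTORS

TRAINING_CAP = 20_000

#: "different complexity levels": member name -> constructor kwargs.
#: rf_* are random forests, gbt_* histogram gradient-boosted trees; sizes are
#: desk-scale defaults, configurable per model.
DEFAULT_HYPER = {
    "rf_simple": {"n_estimators": 150, "max_depth": 5},
    "rf_complex": {"n_estimators": 300, "max_depth": None},
    "gbt_simple": {"max_iter": 100, "max_depth": 2},
    "gbt_complex": {"max_iter": 300, "max_depth": 5},
}


# ---------------------------------------------------------------------------
# training-set assembly

def pseudoabsence_schedule(n_obs: int) -> tuple[int, int]:
    """(n_obs_training, n_PA_training) for a species with n_obs distinct cells."""
    if n_obs < 20:
        raise ValueError("species with fewer than 20 observations are ineligible")
    if n_obs >= 10_000:
        return 10_000, 10_000
    if n_obs >= 1818:
        return n_obs, TRAINING_CAP - n_obs
    if n_obs >= 500:
        return n_obs, 10 * n_obs
    return n_obs, 5000


def range_mask(geometry: BaseGeometry, grid: GridSpec, valid: np.ndarray | None = None) -> np.ndarray:
    """Boolean grid of cell centers covered by the polygon (boundary inclusive)."""
    lon, lat = grid.center_mesh()
    shapely.prepare(geometry)
    inside = shapely.contains_xy(geometry, lon.ravel(), lat.ravel()).reshape(grid.shape)
    on_boundary = shapely.intersects_xy(geometry.boundary, lon.ravel(), lat.ravel()).reshape(grid.shape) \
        if not geometry.is_empty else np.zeros(grid.shape, bool)
    inside = inside | on_boundary
    if valid is not None:
        inside &= np.asarray(valid, dtype=bool)
    return inside


@dataclass
class TrainingSet:
    """Labeled predictor vectors for one species."""

    X: pd.DataFrame  # predictor columns, presences first
    y: np.ndarray  # 1 = presence, 0 = pseudoabsence
    presence_cells: np.ndarray  # (n, 2) row/col of presence rows
    absence_cells: np.ndarray
    n_obs: int  # distinct-cell observation count before subsampling

    @property
    def n_obs_training(self) -> int:
        return int(self.y.sum())

    @property
    def n_pa_training(self) -> int:
        return int((self.y == 0).sum())


def sample_training(
    cells: np.ndarray,
    range_poly: BaseGeometry,
    env: EnvStack,
    seed: int = 0,
    holdout_cells: np.ndarray | None = None,
) -> TrainingSet:
    """Assemble presences and uniform pseudoabsences inside the range.

    Presences are the species' occupied cells that fall inside the range;
    pseudoabsences are drawn uniformly without replacement over unmasked,
    non-presence cells inside the range. ``holdout_cells`` (e.g. a reserved
    evaluation set of known presences) are excluded from pseudoabsence
    candidacy without entering the presences. If the range holds fewer
    candidate cells than the schedule asks for, all of them are used with a
    warning.
    """
    rng = np.random.default_rng(seed)
    grid = env.grid
    in_range = range_mask(range_poly, grid, env.mask)
    cells = np.asarray(cells).reshape(-1, 2)
    keep = in_range[cells[:, 0], cells[:, 1]]
    cells = cells[keep]
    n_obs = len(cells)
    n_obs_tr, n_pa_tr = pseudoabsence_schedule(n_obs)
    if n_obs > n_obs_tr:
        idx = rng.choice(n_obs, size=n_obs_tr, replace=False)
        pres = cells[np.sort(idx)]
    else:
        pres = cells

    candidate = in_range.copy()
    candidate[cells[:, 0], cells[:, 1]] = False  # pseudoabsences exclude presences
    if holdout_cells is not None and len(holdout_cells):
        hc = np.asarray(holdout_cells).reshape(-1, 2)
        candidate[hc[:, 0], hc[:, 1]] = False
    cand_flat = np.flatnonzero(candidate.ravel())
    if len(cand_flat) < n_pa_tr:
        warnings.warn(
            f"only {len(cand_flat)} pseudoabsence candidates for {n_pa_tr} requested; using all",
            stacklevel=2,
        )
        chosen = cand_flat
    else:
        chosen = rng.choice(cand_flat, size=n_pa_tr, replace=False)
    ar, ac = np.unravel_index(chosen, grid.shape)
    absc = np.column_stack([ar, ac])

    def extract(cc: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {v: env.layers[v][cc[:, 0], cc[:, 1]] for v in PREDICTORS}
        )

    X = pd.concat([extract(pres), extract(absc)], ignore_index=True)
    y = np.concatenate([np.ones(len(pres), dtype=int), np.zeros(len(absc), dtype=int)])
    return TrainingSet(X=X, y=y, presence_cells=pres, absence_cells=absc, n_obs=n_obs)


def select_predictors(
    training: TrainingSet,
    n_obs: int,
    all_predictors: list[str] | None = None,
    seed: int = 0,
) -> list[str]:
    """Top-k predictors under the 10-observations-per-predictor rule.

    k = min(9, n_obs // 10). When k < 9, predictors are ranked by
    impurity-based importance from one all-predictor random forest fit on the
    training set; ties break by the fixed predictor order.
    """
    if all_predictors is None:
        all_predictors = list(PREDICTORS)
    k = min(len(all_predictors), n_obs // 10)
    if k >= len(all_predictors):
        return list(all_predictors)
    rf = RandomForestClassifier(n_estimators=200, random_state=_int_seed(seed), n_jobs=1)
    rf.fit(training.X[all_predictors], training.y)
    imp = rf.feature_importances_
    order = np.lexsort((np.arange(len(all_predictors)), -imp))
    return [all_predictors[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# threshold optimization

def max_tss_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Smallest threshold maximizing TSS over the sorted unique scores.

    A point scores "present" when its probability is >= the threshold.
    Returns (threshold, max_tss).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    cand = np.unique(scores)
    # sensitivity(t) = P(pos >= t); specificity(t) = P(neg < t)
    sens = 1.0 - np.searchsorted(pos, cand, side="left") / max(len(pos), 1)
    spec = np.searchsorted(neg, cand, side="left") / max(len(neg), 1)
    tss = sens + spec - 1.0
    best = np.argmax(tss)  # argmax takes the first (smallest) maximizer
    return float(cand[best]), float(tss[best])


def tss_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    pred = np.asarray(scores) >= threshold
    labels = np.asarray(labels).astype(bool)
    sens = pred[labels].mean() if labels.any() else np.nan
    spec = (~pred[~labels]).mean() if (~labels).any() else np.nan
    return float(sens + spec - 1.0)


def _int_seed(seed) -> int:
    """Derive a bounded integer seed from an int or a mixed tuple key."""
    if isinstance(seed, (tuple, list)):
        seed = [
            zlib.crc32(p.encode()) if isinstance(p, str) else int(p) % (2**31)
            for p in seed
        ]
    return int(np.random.default_rng(seed).integers(2**31 - 1))


def _make_members(hyper: dict, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    members = {}
    for name, kw in hyper.items():
        s = int(rng.integers(2**31 - 1))
        if name.startswith("rf"):
            members[name] = RandomForestClassifier(n_jobs=1, random_state=s, **kw)
        else:
            members[name] = HistGradientBoostingClassifier(random_state=s, **kw)
    return members


def _fit_members(members: dict, X: pd.DataFrame, y: np.ndarray) -> dict:
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    for m in members.values():
        m.fit(X, y)
    return members


def _ensemble_proba(members: dict, X: pd.DataFrame) -> np.ndarray:
    probs = [m.predict_proba(X)[:, list(m.classes_).index(1)] for m in members.values()]
    return np.mean(probs, axis=0)


def optimize_threshold_cv(
    training: TrainingSet,
    predictors: list[str],
    hyper: dict | None = None,
    k_folds: int = 3,
    seed: int = 0,
    max_retries: int = 20,
) -> tuple[float, float, float]:
    """Cross-validated max-TSS threshold; returns (threshold, TSS, AUC).

    Folds are assigned at random (redrawn, bounded, until every fold holds
    both classes); out-of-fold ensemble probabilities are pooled, the
    threshold scan runs over their sorted unique values, and AUC is computed
    on the same pooled scores.
    """
    if hyper is None:
        hyper = DEFAULT_HYPER
    rng = np.random.default_rng(seed)
    y = training.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    n = len(y)
    folds = None
    for _ in range(max_retries):
        f = rng.integers(k_folds, size=n)
        if all(len(np.unique(y[f == i])) == 2 for i in range(k_folds)):
            folds = f
            break
    if folds is None:
        raise RuntimeError("could not draw folds containing both classes")
    X = training.X[predictors]
    oof = np.empty(n)
    for i in range(k_folds):
        tr = folds != i
        members = _make_members(hyper, _int_seed((seed, i)))
        _fit_members(members, X[tr], y[tr])
        oof[folds == i] = _ensemble_proba(members, X[folds == i])
    threshold, tss = max_tss_threshold(oof, y)
    auc = float(roc_auc_score(y, oof))
    return threshold, tss, auc


# ---------------------------------------------------------------------------
# rasters

@dataclass
class SuitabilityMap:
    grid: GridSpec
    values: np.ndarray  # float, nan outside range/mask
    valid: np.ndarray  # True where a prediction exists


@dataclass
class BinaryDistribution:
    grid: GridSpec
    values: np.ndarray  # bool; meaningful only where valid
    valid: np.ndarray

    @property
    def suitable(self) -> np.ndarray:
        return self.values & self.valid


def iou(a: BinaryDistribution, b: BinaryDistribution) -> float:
    """Intersection over union of suitable cells; 0 (with warning) if both empty."""
    if a.grid != b.grid:
        raise ValueError("binary maps on different grids")
    A, B = a.suitable, b.suitable
    union = (A | B).sum()
    if union == 0:
        warnings.warn("IoU of two empty maps reported as 0", stacklevel=2)
        return 0.0
    return float((A & B).sum() / union)


# ---------------------------------------------------------------------------
# model / results

class SpeciesDistributionModel:
    """Ensemble niche model for one species.

    Parameters
    ----------
    training : TrainingSet
        Presences and pseudoabsences with predictor vectors.
    predictors : list of str, optional
        Predictor subset; selected by the 10x rule when omitted.
    hyper : dict, optional
        Member hyperparameters (see ``DEFAULT_HYPER``).
    """

    def __init__(
        self,
        training: TrainingSet,
        predictors: list[str] | None = None,
        hyper: dict | None = None,
        species_id: str = "",
    ):
        self.training = training
        self.predictors = predictors
        self.hyper = dict(hyper or DEFAULT_HYPER)
        self.species_id = species_id

    @classmethod
    def from_occurrences(
        cls,
        cells: np.ndarray,
        range_poly: BaseGeometry,
        env: EnvStack,
        seed: int = 0,
        species_id: str = "",
        hyper: dict | None = None,
        holdout_cells: np.ndarray | None = None,
    ) -> "SpeciesDistributionModel":
        """Build the model straight from occupied cells and a range polygon."""
        training = sample_training(cells, range_poly, env, seed=seed, holdout_cells=holdout_cells)
        return cls(training, hyper=hyper, species_id=species_id)

    def fit(self, seed: int = 0, k_folds: int = 3) -> "SDMResults":
        """Select predictors, cross-validate the threshold, refit on all data."""
        predictors = self.predictors
        if predictors is None:
            predictors = select_predictors(self.training, self.training.n_obs, seed=_int_seed((seed, "sel")))
        threshold, tss, auc = optimize_threshold_cv(
            self.training, predictors, self.hyper, k_folds=k_folds, seed=_int_seed((seed, "cv"))
        )
        members = _make_members(self.hyper, _int_seed((seed, "fit")))
        _fit_members(members, self.training.X[predictors], self.training.y)
        return SDMResults(
            model=self,
            members=members,
            predictors=predictors,
            threshold=threshold,
            cv_tss=tss,
            cv_auc=auc,
        )


@dataclass
class SDMResults:
    """Fitted ensemble, selected predictors, threshold and CV diagnostics."""

    model: SpeciesDistributionModel
    members: dict
    predictors: list[str]
    threshold: float
    cv_tss: float
    cv_auc: float

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Ensemble-mean presence probability for predictor rows."""
        return _ensemble_proba(self.members, X[self.predictors])

    def predict_map(
        self,
        env: EnvStack,
        range_poly: BaseGeometry,
        scenario: str = "current",
    ) -> tuple[SuitabilityMap, BinaryDistribution]:
        """Suitability and thresholded occupancy rasters clipped to the range.

        Scenario layers supply the climate; soils are constant. Cells outside
        the range polygon or the land mask carry no data. Binarization uses
        probability >= threshold.
        """
        layers = env.scenario_layers(scenario)
        grid = env.grid
        valid = range_mask(range_poly, grid, env.mask)
        rr, cc = np.nonzero(valid)
        X = pd.DataFrame({v: layers[v][rr, cc] for v in self.predictors})
        p = self.predict_proba(X)
        prob = np.full(grid.shape, np.nan)
        prob[rr, cc] = p
        binary = np.zeros(grid.shape, dtype=bool)
        binary[rr, cc] = p >= self.threshold
        return (
            SuitabilityMap(grid=grid, values=prob, valid=valid),
            BinaryDistribution(grid=grid, values=binary, valid=valid),
        )

    def summary(self) -> str:
        t = self.model.training
        lines = [
            f"Species distribution model {self.model.species_id or '(unnamed)'}",
            "=" * 48,
            f"observations (distinct cells): {t.n_obs}",
            f"presences in training:         {t.n_obs_training}",
            f"pseudoabsences in training:    {t.n_pa_training}",
            f"predictors ({len(self.predictors)}):               {', '.join(self.predictors)}",
            f"ensemble members:              {', '.join(self.members)}",
            f"max-TSS threshold:             {self.threshold:.4f}",
            f"cross-validated TSS:           {self.cv_tss:.4f}",
            f"cross-validated AUC:           {self.cv_auc:.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# recovery of the generating process (synthetic worlds only)

def holdout_recovery(
    cells: np.ndarray,
    range_poly: BaseGeometry,
    env: EnvStack,
    truth_occupancy: np.ndarray,
    true_suit: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
    hyper: dict | None = None,
) -> dict:
    """Score how well the fitted model recovers a known generating process.

    A ``test_fraction`` of the species' occupied cells is reserved before
    training (and shielded from pseudoabsence sampling). Reported are the
    AUC of the predicted suitability against the true occupancy over in-range
    cells the model never saw, and the Spearman rank correlation between
    predicted and true suitability across all in-range cells.
    """
    from scipy.stats import spearmanr

    rng = np.random.default_rng(seed)
    cells = np.asarray(cells).reshape(-1, 2)
    perm = rng.permutation(len(cells))
    n_test = max(1, int(round(test_fraction * len(cells))))
    test = cells[perm[:n_test]]
    train = cells[perm[n_test:]]
    # shield an evaluation background sample so pseudoabsence sampling cannot
    # exhaust the held-out negatives inside small ranges
    in_range = range_mask(range_poly, env.grid, env.mask)
    cand = in_range.copy()
    cand[cells[:, 0], cells[:, 1]] = False
    cand_flat = np.flatnonzero(cand.ravel())
    n_bg = min(2000, len(cand_flat) // 4)
    bg_flat = rng.choice(cand_flat, size=n_bg, replace=False)
    bg = np.column_stack(np.unravel_index(bg_flat, env.grid.shape))
    model = SpeciesDistributionModel.from_occurrences(
        train, range_poly, env, seed=_int_seed((seed, "sample")), hyper=hyper,
        holdout_cells=np.vstack([test, bg]),
    )
    res = model.fit(seed=_int_seed((seed, "fit")))
    suit, _ = res.predict_map(env, range_poly, "current")
    used = np.zeros(env.grid.shape, dtype=bool)
    for cc in (model.training.presence_cells, model.training.absence_cells):
        used[cc[:, 0], cc[:, 1]] = True
    held = suit.valid & ~used
    y = np.asarray(truth_occupancy, bool)[held]
    p = suit.values[held]
    if 0 < y.sum() < len(y):
        auc = float(roc_auc_score(y, p))
    else:
        auc = np.nan
    rho = float(spearmanr(suit.values[suit.valid], np.asarray(true_suit)[suit.valid]).statistic)
    return {
        "auc": auc,
        "rho": rho,
        "n_obs": len(cells),
        "n_test": int(y.sum()),
        "cv_tss": res.cv_tss,
        "cv_auc": res.cv_auc,
    }


# ---------------------------------------------------------------------------
# evaluation against independent plots

def evaluate_plots(
    binary: BinaryDistribution,
    plots: pd.DataFrame,
    range_poly: BaseGeometry,
    min_presences: int = 5,
) -> dict | None:
    """Confusion-matrix skill of a binary map against presence/absence plots.

    Plots outside the range polygon are excluded; returns None (skipped) when
    fewer than ``min_presences`` in-range presences exist. Metrics: TSS,
    precision, recall, false positive rate, false negative rate.
    """
    grid = binary.grid
    lon = plots["lon"].to_numpy()
    lat = plots["lat"].to_numpy()
    shapely.prepare(range_poly)
    inside = shapely.contains_xy(range_poly, lon, lat)
    if not range_poly.is_empty:
        inside |= shapely.intersects_xy(range_poly.boundary, lon, lat)
    df = plots[inside]
    if int(df["present"].sum()) < min_presences:
        return None
    row, col = grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    on = (row >= 0) & (col >= 0)
    df, row, col = df[on], row[on], col[on]
    pred = binary.suitable[row, col]
    obs = df["present"].to_numpy().astype(bool)
    tp = int((pred & obs).sum())
    fn = int((~pred & obs).sum())
    fp = int((pred & ~obs).sum())
    tn = int((~pred & ~obs).sum())
    recall = tp / (tp + fn) if tp + fn else np.nan
    precision = tp / (tp + fp) if tp + fp else np.nan
    fpr = fp / (fp + tn) if fp + tn else np.nan
    specificity = 1.0 - fpr if np.isfinite(fpr) else np.nan
    return {
        "TSS": recall + specificity - 1.0,
        "precision": precision,
        "recall": recall,
        "FPR": fpr,
        "FNR": fn / (tp + fn) if tp + fn else np.nan,
        "n_plots": int(len(df)),
    }
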