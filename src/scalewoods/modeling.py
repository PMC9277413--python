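"""Random-forest modelling protocol: Boruta screening, mtry/ntree tuning,
70/30 evaluation, accuracy metrics and relative importances.

The ensemble is a classical regression random forest -- bootstrap-aggregated
scikit-learn decision trees with ``mtry`` features tried per split -- built
by an explicit bagging loop (:class:`BaggedForest`).  Growing the trees one
at a time exposes the cumulative out-of-bag (OOB) error as a function of the
number of trees, which is exactly the curve the ntree stationarity rule
inspects, without refitting a forest per candidate.

Protocol order per repetition: a 70/30 train/test split is drawn first; the
Boruta screen, the mtry search and the ntree scan all see only the training
portion; the test 30% is untouched until the final metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from scipy.stats import binomtest
from sklearn.tree import DecisionTreeRegressor

from .config import TuningProtocol
from .indices import CATEGORIES, CATEGORY_MAP, PREDICTOR_NAMES

logger = logging.getLogger(__name__)


class BaggedForest:
    """Bootstrap-aggregated regression trees with per-tree OOB tracking."""

    def __init__(self, mtry: int, n_trees: int, seed: int, min_samples_leaf: int = 5):
        self.mtry = mtry
        self.n_trees = n_trees
        self.seed = seed
        self.min_samples_leaf = min_samples_leaf
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_curve_: dict[int, float] = {}

    def fit(self, X: np.ndarray, y: np.ndarray,
            checkpoints: list[int] | None = None) -> "BaggedForest":
        """Grow the ensemble; record cumulative OOB MSE at each checkpoint."""
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        n = len(y)
        rng = np.random.default_rng(self.seed)
        # one sequentially-consumed RandomState for all trees: deterministic,
        # and skips per-tree RandomState construction
        tree_state = np.random.RandomState(int(rng.integers(2**31 - 1)))
        oob_sum = np.zeros(n)
        oob_cnt = np.zeros(n, dtype=np.int64)
        checkpoints = set(checkpoints or [])
        mtry = int(min(max(self.mtry, 1), X.shape[1]))
        with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
            for t in range(self.n_trees):
                idx = rng.integers(0, n, n)
                tree = DecisionTreeRegressor(
                    max_features=mtry, random_state=tree_state,
                    min_samples_leaf=self.min_samples_leaf,
                )
                tree.fit(X[idx], y[idx], check_input=False)
                self.trees.append(tree)
                pred = tree.predict(X, check_input=False)
                oob = np.bincount(idx, minlength=n) == 0
                oob_sum[oob] += pred[oob]
                oob_cnt[oob] += 1
                if (t + 1) in checkpoints:
                    self.oob_curve_[t + 1] = _oob_mse(y, oob_sum, oob_cnt)
        self._oob_sum = oob_sum
        self._oob_cnt = oob_cnt
        self._y = y
        return self

    @property
    def oob_mse_(self) -> float:
        return _oob_mse(self._y, self._oob_sum, self._oob_cnt)

    def predict(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        """Mean prediction of the first ``n_trees`` trees (all by default)."""
        X = np.ascontiguousarray(X, dtype=np.float32)
        use = self.trees if n_trees is None else self.trees[:n_trees]
        with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
            out = np.zeros(len(X))
            for tree in use:
                out += tree.predict(X, check_input=False)
        return out / len(use)

    def feature_importances(self) -> np.ndarray:
        """Mean impurity-decrease importances across trees."""
        return np.mean([t.feature_importances_ for t in self.trees], axis=0)


def _oob_mse(y: np.ndarray, oob_sum: np.ndarray, oob_cnt: np.ndarray) -> float:
    ok = oob_cnt > 0
    if not ok.any():  # pragma: no cover - cannot happen beyond a few trees
        return float("nan")
    resid = y[ok] - oob_sum[ok] / oob_cnt[ok]
    return float(np.mean(resid**2))


# ---------------------------------------------------------------------------
# Boruta all-relevant feature screening

class SelectionError(ValueError):
    """Raised when feature screening is impossible (e.g. constant response)."""


def boruta_select(X: pd.DataFrame, y: np.ndarray, rng: np.random.Generator,
                  alpha: float = 0.05, max_iter: int = 100,
                  n_estimators: int = 50, details: dict | None = None) -> list[str]:
    """All-relevant feature screen against permuted shadow features.

    Each iteration appends a shuffled copy of every still-active feature,
    fits a random forest, and scores a "hit" for features whose importance
    beats the best shadow.  A two-sided binomial test at ``alpha`` confirms
    or rejects features; tentative features at the end are dropped.  If
    fewer than two features are confirmed the screen falls back to the full
    feature set (logged).  A ``details`` dict, if given, receives the raw
    confirmed / rejected / tentative partition.
    """
    if X.shape[1] < 2:
        raise SelectionError("need at least 2 candidate features")
    if X.shape[0] < 20:
        raise SelectionError("need at least 20 rows for screening")
    y = np.asarray(y, float)
    if np.ptp(y) == 0:
        raise SelectionError("response is constant")

    names = list(X.columns)
    Xv = X.to_numpy(float)
    active = np.ones(len(names), bool)      # not yet rejected
    confirmed = np.zeros(len(names), bool)
    hits = np.zeros(len(names), int)

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        idx = np.flatnonzero(active & ~confirmed)
        if idx.size == 0:
            n_iter -= 1
            break
        cand = np.flatnonzero(active)
        shadows = Xv[:, cand].copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        design = np.hstack([Xv[:, cand], shadows])
        forest = BaggedForest(
            mtry=max(1, round(design.shape[1] / 3)), n_trees=n_estimators,
            seed=int(rng.integers(2**31 - 1)),
        ).fit(design, y)
        imp = forest.feature_importances()
        shadow_max = imp[len(cand):].max()
        hits[cand[imp[: len(cand)] > shadow_max]] += 1

        for f in np.flatnonzero(active & ~confirmed):
            p_hi = binomtest(hits[f], n_iter, 0.5, alternative="greater").pvalue
            p_lo = binomtest(hits[f], n_iter, 0.5, alternative="less").pvalue
            if p_hi < alpha / 2:
                confirmed[f] = True
            elif p_lo < alpha / 2:
                active[f] = False

    selected = [names[i] for i in np.flatnonzero(confirmed)]
    if details is not None:
        details["confirmed"] = selected
        details["rejected"] = [names[i] for i in np.flatnonzero(~active)]
        details["tentative"] = [names[i] for i in np.flatnonzero(active & ~confirmed)]
        details["n_iter"] = n_iter
    logger.debug("boruta: %d confirmed of %d after %d iterations",
                 len(selected), len(names), n_iter)
    if len(selected) < 2:
        logger.info("boruta confirmed %d features; falling back to all %d",
                    len(selected), len(names))
        return names
    return selected


# ---------------------------------------------------------------------------
# hyper-parameter tuning

def tune_mtry(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
              step_factor: float = 2.0, improve: float = 0.05,
              ntree_try: int = 100, evaluations: dict | None = None) -> int:
    """tuneRF-style search for the OOB-error-minimising mtry.

    Starts at round(p/3) and steps by ``step_factor`` in each direction while
    the relative OOB improvement exceeds ``improve``; returns the evaluated
    candidate with the smallest OOB error, clipped to [1, p].  If
    ``evaluations`` is a dict it is filled with every candidate's OOB error.
    """
    X = np.asarray(X, float)
    p = X.shape[1]
    if p == 1:
        return 1

    cache: dict[int, float] = evaluations if evaluations is not None else {}

    def oob(m: int) -> float:
        if m not in cache:
            cache[m] = BaggedForest(m, ntree_try, int(rng.integers(2**31 - 1))).fit(X, y).oob_mse_
        return cache[m]

    start = int(np.clip(round(p / 3), 1, p))
    best = oob(start)
    for direction in (-1, 1):
        m, err = start, best
        while True:
            nxt = int(np.clip(round(m * step_factor) if direction > 0
                              else max(1, int(m / step_factor)), 1, p))
            if nxt == m or nxt in cache:
                break
            nerr = oob(nxt)
            if err - nerr <= improve * err:
                break
            m, err = nxt, nerr
    return min(cache, key=cache.get)


def first_stationary(errors: list[float], candidates: list[int],
                     threshold: float, increment: float) -> int:
    """First candidate whose forward error difference drops below threshold.

    If no consecutive difference qualifies, the threshold is escalated by
    ``increment`` and the scan repeats; guaranteed to terminate because the
    threshold grows without bound.  A single-candidate list (no forward
    difference to inspect) returns that candidate.
    """
    diffs = np.abs(np.diff(np.asarray(errors, float)))
    finite = diffs[np.isfinite(diffs)]
    if finite.size == 0:
        return candidates[0] if len(candidates) == 1 else candidates[-1]
    while True:
        below = np.flatnonzero(diffs < threshold)
        if below.size:
            return candidates[int(below[0])]
        threshold += increment


def select_ntree(X: np.ndarray, y: np.ndarray, mtry: int,
                 protocol: TuningProtocol, rng: np.random.Generator,
                 forest_out: list | None = None) -> int:
    """Scan the OOB error over the ntree candidates and apply the
    stationarity rule.

    One ensemble is grown to the largest candidate with checkpointed
    cumulative OOB error -- the same curve R's randomForest plots.  If
    ``forest_out`` is given, the grown ensemble is appended so callers can
    reuse its tree prefix instead of refitting.
    """
    candidates = protocol.ntree_candidates
    forest = BaggedForest(mtry, candidates[-1], int(rng.integers(2**31 - 1)))
    forest.fit(X, y, checkpoints=candidates)
    if forest_out is not None:
        forest_out.append(forest)
    errors = [forest.oob_curve_[c] for c in candidates]
    return first_stationary(errors, candidates,
                            protocol.stationarity_threshold,
                            protocol.threshold_increment)


# ---------------------------------------------------------------------------
# evaluation

METRIC_NAMES = ["ME", "MAE", "MRE", "RMSE", "rRMSE", "R2"]


def accuracy_metrics(obs: np.ndarray, est: np.ndarray) -> dict[str, float]:
    """The six goodness-of-fit criteria on a test set.

    ME and MRE are signed; rRMSE is RMSE as a percentage of the mean
    observation; R2 is the standard coefficient of determination.
    """
    obs = np.asarray(obs, float)
    est = np.asarray(est, float)
    resid = obs - est
    n = len(obs)
    rmse = float(np.sqrt(np.mean(resid**2)))
    mean_obs = float(np.mean(obs))
    ss_tot = float(np.sum((obs - mean_obs) ** 2))
    return {
        "ME": float(np.mean(resid)),
        "MAE": float(np.mean(np.abs(resid))),
        "MRE": float(np.sum(resid) / np.sum(obs)) if np.sum(obs) != 0 else float("nan"),
        "RMSE": rmse,
        "rRMSE": 100.0 * rmse / mean_obs if mean_obs != 0 else float("nan"),
        "R2": 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan"),
    }


@dataclass
class ModelResult:
    selected_features: list[str]
    mtry: int
    ntree: int
    metrics: dict[str, float]
    importance: dict[str, float]           # per-feature relative importance, %
    category_importance: dict[str, float]  # per-category, %


def train_test_split_indices(n: int, train_fraction: float,
                             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return perm[:n_train], perm[n_train:]


def permutation_importance_raw(forest: BaggedForest, X: np.ndarray, y: np.ndarray,
                               rng: np.random.Generator, n_repeats: int = 3,
                               n_trees: int | None = None) -> np.ndarray:
    """Mean MSE increase when each feature column is shuffled.

    All shuffled copies are stacked into one prediction batch so the forest
    is traversed once.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    batches = []
    for j in range(p):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            batches.append(Xp)
    batches.append(X)
    preds = forest.predict(np.vstack(batches), n_trees=n_trees)
    preds = preds.reshape(p * n_repeats + 1, n)
    base_mse = np.mean((y - preds[-1]) ** 2)
    perm_mse = np.mean((y[None, :] - preds[:-1]) ** 2, axis=1).reshape(p, n_repeats)
    return perm_mse.mean(axis=1) - base_mse


def fit_evaluate(X: pd.DataFrame, y: np.ndarray, mtry: int, ntree: int,
                 rng: np.random.Generator, split: float = 0.7,
                 split_indices: tuple[np.ndarray, np.ndarray] | None = None,
                 forest: BaggedForest | None = None,
                 importance_repeats: int = 3) -> ModelResult:
    """Train on the 70% split, evaluate the six metrics on the held-out 30%.

    ``split_indices`` lets a caller reuse a split drawn before tuning;
    ``forest`` lets it reuse an already-grown ensemble whose first ``ntree``
    trees constitute the selected model.
    """
    if len(X) < 10:
        raise ValueError("need at least 10 rows to fit and evaluate")
    names = list(X.columns)
    Xv = X.to_numpy(float)
    y = np.asarray(y, float)
    if split_indices is None:
        split_indices = train_test_split_indices(len(y), split, rng)
    tr, te = split_indices
    if len(te) < 2:
        raise ValueError("test set smaller than 2 rows")

    if forest is None:
        forest = BaggedForest(mtry, ntree, int(rng.integers(2**31 - 1)))
        forest.fit(Xv[tr], y[tr])
    est = forest.predict(Xv[te], n_trees=ntree)
    metrics = accuracy_metrics(y[te], est)

    raw = permutation_importance_raw(forest, Xv[te], y[te], rng,
                                     n_repeats=importance_repeats, n_trees=ntree)
    importance, category = relative_importance(dict(zip(names, raw)), CATEGORY_MAP)
    return ModelResult(selected_features=names, mtry=mtry, ntree=ntree,
                       metrics=metrics, importance=importance,
                       category_importance=category)


def relative_importance(raw: dict[str, float],
                        category_map: dict[str, str]) -> tuple[dict[str, float], dict[str, float]]:
    """Normalise raw importances to percentages and sum them per category.

    Negative raw importances are clipped to zero (logged); features absent
    from ``raw`` (screened out) carry 0.  An all-zero vector is flagged and
    returned as zeros.
    """
    clipped = {}
    for name, v in raw.items():
        if v < 0:
            logger.debug("negative importance %.4g for %s clipped to 0", v, name)
            v = 0.0
        clipped[name] = v
    total = sum(clipped.values())
    known = [n for n in PREDICTOR_NAMES if n in category_map]
    per_feature = {name: 0.0 for name in known}
    per_feature.update({name: 0.0 for name in clipped})
    if total <= 0:
        logger.warning("all permutation importances are zero; relative shares undefined")
    else:
        for name, v in clipped.items():
            per_feature[name] = float(100.0 * v / total)
    per_category = {c: 0.0 for c in CATEGORIES}
    for name, share in per_feature.items():
        cat = category_map.get(name)
        if cat is not None:
            per_category.setdefault(cat, 0.0)
            per_category[cat] = float(per_category[cat] + share)
    return per_feature, per_category


def run_protocol(features: pd.DataFrame, protocol: TuningProtocol,
                 rng: np.random.Generator) -> ModelResult:
    """Full per-repetition pipeline on one quadrat feature table.

    Split -> Boruta screen -> mtry search -> ntree stationarity scan ->
    final fit and test-set evaluation, with every stage before the metrics
    restricted to the training rows.
    """
    X = features[PREDICTOR_NAMES]
    y = features["P"].to_numpy(float)
    tr, te = train_test_split_indices(len(y), protocol.train_fraction, rng)

    selected = boruta_select(X.iloc[tr], y[tr], rng,
                             alpha=protocol.boruta_alpha,
                             max_iter=protocol.boruta_max_iter,
                             n_estimators=protocol.boruta_n_estimators)
    Xs = X[selected]
    mtry = tune_mtry(Xs.iloc[tr].to_numpy(float), y[tr], rng,
                     step_factor=protocol.mtry_step_factor,
                     improve=protocol.mtry_improve,
                     ntree_try=protocol.mtry_ntree_try)
    grown: list[BaggedForest] = []
    ntree = select_ntree(Xs.iloc[tr].to_numpy(float), y[tr], mtry, protocol, rng,
                         forest_out=grown)
    result = fit_evaluate(Xs, y, mtry, ntree, rng,
                          split_indices=(tr, te), forest=grown[0],
                          importance_repeats=protocol.importance_repeats)
    result.selected_features = selected
    return result
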