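"""Supervised distance: task-aware feature redundancy and selection.

The supervised distance between features i and j asks how well one
feature can reproduce the other's univariate relationship with the label:

    supervised R2(i, j) = max(0, 1 - mean((P_i - P_i^j)^2 / var(P_i)))
    supervised distance(i, j) = max(1 - R2(i, j), 1 - R2(j, i))

where P_i is the output of a default-hyperparameter univariate
gradient-boosted model of the label from feature i (probability space by
default), and P_i^j the output of a univariate squared-error model of P_i
from feature j.  Distance 0 means the pair is fully redundant for the
task; distance 1 means not redundant at all.  A feature whose univariate
prediction is constant (var = 0) carries no label information and is
defined to be non-redundant with everything (R2 = 0 in that direction).

Complete-linkage hierarchical clustering over the distance matrix finds
redundant groups, and the recursive selection procedure keeps one (the
most important by mean |phi|) member per cluster, shrinking the feature
set by a fixed step per iteration while always retaining the
demographic anchors (age and sex by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from xgboost import XGBClassifier, XGBRegressor

from .containers import EvaluationResult, FeatureTable
from .models import TrainedModel, evaluate_auroc, fit_gbt, predict_risk
from .shapley import attribute, importance


@dataclass
class DistanceMatrix:
    """Symmetric supervised-distance matrix with optional stored
    prediction vectors for exact arithmetic re-derivation."""

    features: list[str]
    values: np.ndarray  # [d, d], zero diagonal
    r2: np.ndarray  # [d, d], directed supervised R2(i, j)
    prediction_i: dict[str, np.ndarray] = field(default_factory=dict)
    prediction_ij: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.features)

    def lookup(self, i: str, j: str) -> float:
        a, b = self.features.index(i), self.features.index(j)
        return float(self.values[a, b])


@dataclass
class FeatureClustering:
    features: list[str]
    linkage_matrix: np.ndarray
    assignment: dict[str, int]

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for f, c in self.assignment.items():
            out.setdefault(c, []).append(f)
        return out


@dataclass
class SelectionRecord:
    features: list[str]
    evaluation: EvaluationResult
    min_supervised_distance: float


# ---------------------------------------------------------------------------
# univariate models (library defaults, per the method's definition)


def _univariate_label_prediction(
    x: np.ndarray, y: np.ndarray, seed: int, output: str
) -> np.ndarray:
    m = XGBClassifier(n_jobs=1, random_state=seed, eval_metric="logloss")
    m.fit(x.reshape(-1, 1), y)
    if output == "probability":
        return m.predict_proba(x.reshape(-1, 1))[:, 1].astype(np.float64)
    if output == "margin":
        return m.predict(x.reshape(-1, 1), output_margin=True).astype(np.float64)
    raise ValueError(f"unknown output space {output!r}")


def _univariate_regression(x: np.ndarray, target: np.ndarray, seed: int) -> np.ndarray:
    m = XGBRegressor(n_jobs=1, random_state=seed)
    m.fit(x.reshape(-1, 1), target)
    return m.predict(x.reshape(-1, 1)).astype(np.float64)


def r2_from_predictions(pred_i: np.ndarray, pred_ij: np.ndarray) -> float:
    """The supervised R2 arithmetic, exposed for exact re-derivation."""
    var = float(np.var(pred_i))
    if var == 0.0:
        return 0.0
    return max(0.0, 1.0 - float(np.mean((pred_i - pred_ij) ** 2 / var)))


def supervised_r2(
    xi: np.ndarray,
    xj: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray | None = None,
    seed: int = 0,
    output: str = "probability",
) -> float:
    """Directed supervised R2(i, j): how well feature j reproduces
    feature i's univariate label prediction."""
    xi, xj, y = _restrict(xi, xj, labels, train_idx)
    pred_i = _univariate_label_prediction(xi, y, seed, output)
    if np.var(pred_i) == 0.0:
        return 0.0
    pred_ij = _univariate_regression(xj, pred_i, seed)
    return r2_from_predictions(pred_i, pred_ij)


def supervised_distance(
    xi: np.ndarray,
    xj: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray | None = None,
    seed: int = 0,
    output: str = "probability",
) -> float:
    """Symmetric supervised distance: 0 = redundant, 1 = not redundant."""
    r_ij = supervised_r2(xi, xj, labels, train_idx, seed, output)
    r_ji = supervised_r2(xj, xi, labels, train_idx, seed, output)
    return max(1.0 - r_ij, 1.0 - r_ji)


def _restrict(xi, xj, labels, train_idx):
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    y = np.asarray(labels)
    if train_idx is not None:
        idx = np.asarray(train_idx)
        xi, xj, y = xi[idx], xj[idx], y[idx]
    return xi, xj, y


def distance_matrix(
    table: FeatureTable,
    labels: np.ndarray | pd.Series,
    train_idx: np.ndarray | None = None,
    features: Sequence[str] | None = None,
    seed: int = 0,
    output: str = "probability",
    keep_predictions: bool = False,
) -> DistanceMatrix:
    """All-pairs supervised-distance matrix.

    The univariate label prediction P_i of each feature is fitted once and
    reused across all pairs involving i, which by construction gives
    identical values to naive one-pair-at-a-time recomputation.
    """
    feats = list(features) if features is not None else table.features
    if len(feats) < 2:
        raise ValueError("need at least two features")
    X = table.values(feats)
    y = np.asarray(labels).astype(int)
    if train_idx is not None:
        idx = np.asarray(train_idx)
        X, y = X[idx], y[idx]
    d = len(feats)
    preds = {}
    for a, f in enumerate(feats):
        preds[f] = _univariate_label_prediction(X[:, a], y, seed, output)
    r2 = np.ones((d, d))
    for a, fi in enumerate(feats):
        for b, fj in enumerate(feats):
            if a == b:
                continue
            if np.var(preds[fi]) == 0.0:
                r2[a, b] = 0.0
                continue
            pred_ij = _univariate_regression(X[:, b], preds[fi], seed)
            r2[a, b] = r2_from_predictions(preds[fi], pred_ij)
    dist = np.maximum(1.0 - r2, 1.0 - r2.T)
    np.fill_diagonal(dist, 0.0)
    dm = DistanceMatrix(feats, dist, r2)
    if keep_predictions:
        dm.prediction_i = preds
        for a, fi in enumerate(feats):
            for b, fj in enumerate(feats):
                if a != b and np.var(preds[fi]) > 0.0:
                    dm.prediction_ij[(fi, fj)] = _univariate_regression(
                        X[:, b], preds[fi], seed
                    )
    return dm


# ---------------------------------------------------------------------------
# clustering & selection


def cluster_features(dm: DistanceMatrix, k: int) -> FeatureClustering:
    """Complete-linkage agglomeration on the supervised-distance matrix,
    cut into k flat clusters."""
    d = len(dm.features)
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}]")
    if d == 1:
        return FeatureClustering(list(dm.features), np.empty((0, 4)), {dm.features[0]: 1})
    condensed = squareform(dm.values, checks=False)
    Z = linkage(condensed, method="complete")
    flat = fcluster(Z, t=k, criterion="maxclust")
    return FeatureClustering(list(dm.features), Z, dict(zip(dm.features, flat.tolist())))


class _PairCache:
    """Caches directed univariate fits across selection iterations."""

    def __init__(self, table, labels, train_idx, seed, output):
        feats = table.features
        X = table.values(feats)
        y = np.asarray(labels).astype(int)
        if train_idx is not None:
            idx = np.asarray(train_idx)
            X, y = X[idx], y[idx]
        self.X = X
        self.y = y
        self.col = {f: a for a, f in enumerate(feats)}
        self.seed = seed
        self.output = output
        self._pred: dict[str, np.ndarray] = {}
        self._r2: dict[tuple[str, str], float] = {}

    def pred(self, f: str) -> np.ndarray:
        if f not in self._pred:
            self._pred[f] = _univariate_label_prediction(
                self.X[:, self.col[f]], self.y, self.seed, self.output
            )
        return self._pred[f]

    def r2(self, fi: str, fj: str) -> float:
        key = (fi, fj)
        if key not in self._r2:
            p = self.pred(fi)
            if np.var(p) == 0.0:
                self._r2[key] = 0.0
            else:
                pij = _univariate_regression(self.X[:, self.col[fj]], p, self.seed)
                self._r2[key] = r2_from_predictions(p, pij)
        return self._r2[key]

    def distance(self, fi: str, fj: str) -> float:
        return max(1.0 - self.r2(fi, fj), 1.0 - self.r2(fj, fi))

    def matrix(self, feats: Sequence[str]) -> DistanceMatrix:
        d = len(feats)
        r2 = np.ones((d, d))
        for a, fi in enumerate(feats):
            for b, fj in enumerate(feats):
                if a != b:
                    r2[a, b] = self.r2(fi, fj)
        dist = np.maximum(1.0 - r2, 1.0 - r2.T)
        np.fill_diagonal(dist, 0.0)
        return DistanceMatrix(list(feats), dist, r2)


def min_pairwise_distance(cache: _PairCache, feats: Sequence[str]) -> float:
    best = 1.0
    fl = list(feats)
    for a in range(len(fl)):
        for b in range(a + 1, len(fl)):
            best = min(best, cache.distance(fl[a], fl[b]))
    return best


def sd_feature_selection(
    table: FeatureTable,
    labels: np.ndarray | pd.Series,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    always_keep: Sequence[str] = ("age", "sex"),
    step: int = 5,
    grid: dict | None = None,
    n_boot: int = 200,
    seed: int = 0,
    output: str = "probability",
    max_background: int = 64,
) -> list[SelectionRecord]:
    """Supervised-distance-based recursive feature selection.

    Each iteration refits the model, ranks features by mean absolute
    attribution, clusters the non-anchor features into (current - step)
    groups on supervised distance, and keeps each cluster's most important
    member plus the anchors.  The trajectory records the feature set, its
    held-out bootstrap AUROC and the minimum pairwise supervised distance
    within the set; iteration stops once the non-anchor features form a
    single cluster.  Pair distances are cached; clustering is re-run on
    each surviving set.
    """
    feats = list(table.features)
    missing = [f for f in always_keep if f not in feats]
    if missing:
        raise ValueError(f"always-keep features absent: {missing}")
    y = np.asarray(labels).astype(int)
    cache = _PairCache(table, labels, train_idx, seed, output)
    train_tab = table.subset_rows(train_idx)
    test_tab = table.subset_rows(test_idx)
    grid = grid if grid is not None else {"max_depth": [3], "n_estimators": [100]}

    current = feats
    records: list[SelectionRecord] = []

    def evaluate(fset: list[str]) -> tuple[SelectionRecord, TrainedModel]:
        model = fit_gbt(train_tab, y[train_idx], grid=grid, seed=seed, features=fset)
        scores = predict_risk(model, test_tab)
        ev = evaluate_auroc(scores, y[test_idx], n_boot=n_boot, seed=seed)
        return SelectionRecord(list(fset), ev, min_pairwise_distance(cache, fset)), model

    rec, model = evaluate(current)
    records.append(rec)
    while True:
        others = [f for f in current if f not in always_keep]
        n_groups = len(others) - step
        if n_groups < 1:
            n_groups = 1
        attr = attribute(
            model, train_tab.subset_features(current), max_background=max_background, seed=seed
        )
        rank = importance(attr).rank_of()
        clustering = cluster_features(cache.matrix(others), n_groups)
        picks = []
        for members in clustering.clusters().values():
            picks.append(min(members, key=lambda f: (rank[f], f)))
        current = sorted(set(picks) | set(always_keep), key=feats.index)
        rec, model = evaluate(current)
        records.append(rec)
        if n_groups == 1:
            break
    return records
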