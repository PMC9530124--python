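"""Gradient-boosted-tree mortality models, splits and AUROC evaluation.

Conventions: an 80/20 random split or a temporal split on the enrollment
cycle; hyperparameters chosen by grid search with stratified 5-fold
cross-validation on the training split; performance measured as AUROC with
a 1000-replicate percentile bootstrap over test subjects.  Missing values
are passed natively to the tree learner; the regularized logistic baseline
(the linear comparison model) median-imputes them first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .containers import EvaluationResult, FeatureTable

# Default grid; deliberately small and explicitly a placeholder — override
# via the ``grid`` argument for serious runs.
DEFAULT_GRID = {
    "max_depth": [3, 6],
    "learning_rate": [0.1, 0.05],
    "n_estimators": [100, 500],
    "min_child_weight": [1, 10],
}

_XGB_FIXED = dict(
    tree_method="hist",
    n_jobs=1,
    eval_metric="logloss",
)


@dataclass
class TrainedModel:
    """A fitted classifier plus the contract needed downstream.

    ``kind`` is ``"gbt"`` for the tree ensemble (margin = log-odds,
    probability = sigmoid(margin)) or ``"linear"`` for the logistic
    baseline (margin = linear predictor).
    """

    model: object
    features: list[str]
    kind: str = "gbt"
    params: dict = field(default_factory=dict)
    tuning_record: list = field(default_factory=list)

    def margin(self, table: FeatureTable | pd.DataFrame) -> np.ndarray:
        X = _matrix(table, self.features)
        if self.kind == "gbt":
            return self.model.predict(X, output_margin=True).astype(np.float64)
        return self.model.decision_function(X).astype(np.float64)


def _matrix(table: FeatureTable | pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    if isinstance(table, FeatureTable):
        return table.values(features)
    absent = [c for c in features if c not in table.columns]
    if absent:
        raise KeyError(f"features not in table: {absent}")
    return table[list(features)].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# splits


def split_cohort(
    table: FeatureTable,
    mode: str = "random_80_20",
    seed: int = 0,
    cutoff: int | None = None,
    test_size: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test partition as integer row indices.

    ``mode="random_80_20"`` shuffles reproducibly; ``mode="temporal"``
    assigns all cycles <= ``cutoff`` to training.
    """
    n = table.n_subjects
    if mode == "random_80_20":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_test = int(round(n * test_size))
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    if mode == "temporal":
        if table.cycle is None:
            raise ValueError("temporal split requires a cycle column")
        if cutoff is None:
            raise ValueError("temporal split requires a cutoff")
        cyc = np.asarray(table.cycle)
        if cutoff < cyc.min() or cutoff >= cyc.max():
            raise ValueError(
                f"cutoff {cutoff} outside usable cycle range "
                f"[{cyc.min()}, {cyc.max() - 1}]"
            )
        train = np.flatnonzero(cyc <= cutoff)
        test = np.flatnonzero(cyc > cutoff)
        return train, test
    raise ValueError(f"unknown split mode {mode!r}")


# ---------------------------------------------------------------------------
# model fitting


def _check_training_inputs(X: np.ndarray, y: np.ndarray, features: Sequence[str]) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    all_missing = np.flatnonzero(np.all(np.isnan(X), axis=0))
    if all_missing.size:
        bad = [features[i] for i in all_missing]
        raise ValueError(f"features with all-missing values: {bad}")


def fit_gbt(
    table: FeatureTable,
    labels: np.ndarray | pd.Series,
    grid: dict | Sequence[dict] | None = None,
    folds: int = 5,
    seed: int = 0,
    features: Sequence[str] | None = None,
    scale_pos_weight: float | None = None,
) -> TrainedModel:
    """Grid-search a gradient-boosted-tree classifier with stratified
    k-fold cross-validated AUROC; refit the best point on all rows.

    Ties are broken by grid order (first wins).  The full tuning record
    (grid point, per-fold AUROCs, mean) is retained on the result.
    """
    feats = list(features) if features is not None else table.features
    X = _matrix(table, feats)
    y = np.asarray(labels).astype(int)
    _check_training_inputs(X, y, feats)
    points = list(ParameterGrid(grid if grid is not None else DEFAULT_GRID))
    if not points:
        raise ValueError("empty hyperparameter grid")

    extra = {} if scale_pos_weight is None else {"scale_pos_weight": scale_pos_weight}
    record = []
    best_i, best_score = 0, -np.inf
    if len(points) > 1:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(cv.split(X, y))
        for i, p in enumerate(points):
            fold_scores = []
            for tr, va in splits:
                m = XGBClassifier(random_state=seed, **_XGB_FIXED, **extra, **p)
                m.fit(X[tr], y[tr])
                fold_scores.append(roc_auc_score(y[va], m.predict_proba(X[va])[:, 1]))
            mean = float(np.mean(fold_scores))
            record.append({"params": p, "fold_auroc": fold_scores, "mean_auroc": mean})
            if mean > best_score:
                best_i, best_score = i, mean
    else:
        record.append({"params": points[0], "fold_auroc": [], "mean_auroc": None})

    best = points[best_i]
    model = XGBClassifier(random_state=seed, **_XGB_FIXED, **extra, **best)
    model.fit(X, y)
    return TrainedModel(model, feats, "gbt", dict(best), record)


def fit_linear_baseline(
    table: FeatureTable,
    labels: np.ndarray | pd.Series,
    seed: int = 0,
    features: Sequence[str] | None = None,
    C: float = 1.0,
) -> TrainedModel:
    """Regularized logistic regression with median imputation and scaling.

    Shares the predict/evaluate interfaces of the tree model so the two can
    be compared head-to-head.
    """
    feats = list(features) if features is not None else table.features
    X = _matrix(table, feats)
    y = np.asarray(labels).astype(int)
    _check_training_inputs(X, y, feats)
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(C=C, max_iter=2000, random_state=seed)),
        ]
    )
    pipe.fit(X, y)
    return TrainedModel(pipe, feats, "linear", {"C": C})


def predict_risk(model: TrainedModel, table: FeatureTable | pd.DataFrame) -> np.ndarray:
    """Predicted event probability; equals sigmoid of the margin output."""
    return expit(model.margin(table))


# ---------------------------------------------------------------------------
# evaluation


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative, ties 1/2."""
    return float(roc_auc_score(np.asarray(labels).astype(int), np.asarray(scores)))


def evaluate_auroc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    stratum_mask: np.ndarray | None = None,
    stratum: str | None = None,
) -> EvaluationResult:
    """Point AUROC plus a percentile 95% bootstrap interval over subjects."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if stratum_mask is not None:
        mask = np.asarray(stratum_mask, dtype=bool)
        s, y = s[mask], y[mask]
    if len(np.unique(y)) < 2:
        raise ValueError(f"stratum {stratum!r}: only one class present")
    point = auroc(s, y)
    rng = np.random.default_rng(seed)
    n = len(y)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():  # degenerate resample: redraw is biased; record point
            reps[b] = point
            continue
        reps[b] = roc_auc_score(yb, s[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    lo, hi = min(lo, point), max(hi, point)
    return EvaluationResult(point, n_boot, float(lo), float(hi), reps, stratum)
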