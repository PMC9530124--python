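"""Tiered, cost-aware mortality risk scores.

A risk score is simply the predicted 5-year (or other horizon) mortality
probability of a tree model trained on a restricted feature pool — the
pool reflecting who can collect the features:

* ``public``: demographics + examination + questionnaire (collectable at
  home; no laboratory features);
* ``professional``: demographics + laboratory;
* ``panel``: demographics + an explicit named laboratory panel;
* ``all``: everything.

Within a pool, recursive feature elimination by mean absolute Shapley
attribution trades collection cost against accuracy: refit, rank, drop
the ``step`` least-important features, repeat.  Scores are evaluated by
bootstrap AUROC overall and per sex stratum, plus temporal validation on
later enrollment cycles.  Individualized explanations convert log-odds
attributions to probability space by proportional rescaling so that
``base risk + contributions = risk score`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import EvaluationResult, FeatureTable
from .models import TrainedModel, evaluate_auroc, fit_gbt, predict_risk
from .shapley import attribute, importance

TIER_ROLES = {
    "public": ("demographic", "examination", "questionnaire"),
    "professional": ("demographic", "laboratory"),
    "all": ("demographic", "examination", "laboratory", "questionnaire"),
}


@dataclass(frozen=True)
class FeatureTier:
    """Admissible feature pool for one class of users."""

    name: str
    panel: tuple[str, ...] = ()  # explicit features for the "panel" tier

    def admissible(self, table: FeatureTable) -> list[str]:
        if self.name == "panel":
            if not self.panel:
                raise ValueError("panel tier needs an explicit feature list")
            demo = table.features_by_role(["demographic"])
            missing = [f for f in self.panel if f not in table.features]
            if missing:
                raise ValueError(f"panel features absent from table: {missing}")
            return demo + [f for f in self.panel if f not in demo]
        if self.name not in TIER_ROLES:
            raise ValueError(f"unknown tier {self.name!r}")
        return table.features_by_role(TIER_ROLES[self.name])


@dataclass
class RFEStep:
    size: int
    features: list[str]  # ordered by descending importance
    evaluation: EvaluationResult


@dataclass
class RiskScoreModel:
    model: TrainedModel
    features: list[str]
    tier: str
    evaluations: dict[str, EvaluationResult] = field(default_factory=dict)
    base_risk: float = float("nan")  # mean predicted risk over training set
    train_cycles: tuple[int, ...] = ()


@dataclass
class IndividualExplanation:
    subject_id: object
    risk_score: float
    base_value: float  # mean risk score
    contributions: pd.Series  # probability-space, signed, indexed by feature
    feature_values: pd.Series

    def top_features(self, n: int = 5) -> pd.Series:
        return self.contributions.reindex(
            self.contributions.abs().sort_values(ascending=False).index
        ).head(n)


# ---------------------------------------------------------------------------
# recursive feature elimination


def rfe_by_importance(
    table: FeatureTable,
    labels: np.ndarray | pd.Series,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    tier: FeatureTier,
    step: int = 5,
    min_size: int = 5,
    record_sizes: Sequence[int] | None = None,
    grid: dict | None = None,
    n_boot: int = 200,
    seed: int = 0,
    max_background: int = 64,
) -> list[RFEStep]:
    """Shapley-importance recursive feature elimination over a tier pool.

    Records (size, importance-ordered features, bootstrap AUROC) at every
    iteration (or only at ``record_sizes``), dropping the ``step`` least
    important features each round until ``min_size`` is reached.
    """
    pool = tier.admissible(table)
    if not pool:
        raise ValueError(f"tier {tier.name!r} admits no features")
    if record_sizes is not None and max(record_sizes) > len(pool):
        raise ValueError("requested size exceeds the tier pool")
    y = np.asarray(labels).astype(int)
    grid = grid if grid is not None else {"max_depth": [3], "n_estimators": [100]}
    train_tab = table.subset_rows(train_idx)
    test_tab = table.subset_rows(test_idx)

    steps: list[RFEStep] = []
    current = list(pool)
    while True:
        model = fit_gbt(train_tab, y[train_idx], grid=grid, seed=seed, features=current)
        attr = attribute(model, train_tab, max_background=max_background, seed=seed)
        ranked = importance(attr).features
        if record_sizes is None or len(current) in set(record_sizes):
            scores = predict_risk(model, test_tab)
            ev = evaluate_auroc(scores, y[test_idx], n_boot=n_boot, seed=seed)
            steps.append(RFEStep(len(current), ranked, ev))
        if len(current) <= min_size:
            break
        keep = max(min_size, len(current) - step)
        current = ranked[:keep]
    return steps


def build_risk_score(
    table: FeatureTable,
    labels: np.ndarray | pd.Series,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    tier: FeatureTier,
    size: int,
    step: int = 5,
    grid: dict | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    sex_column: str = "sex",
    max_background: int = 64,
) -> RiskScoreModel:
    """Train a size-constrained risk score for one tier.

    The feature set comes from RFE down to ``size``; evaluations are
    attached overall and per sex stratum.
    """
    steps = rfe_by_importance(
        table,
        labels,
        train_idx,
        test_idx,
        tier,
        step=step,
        min_size=size,
        record_sizes=[size],
        grid=grid,
        n_boot=n_boot,
        seed=seed,
        max_background=max_background,
    )
    selected = steps[-1].features[:size]
    y = np.asarray(labels).astype(int)
    train_tab = table.subset_rows(train_idx)
    test_tab = table.subset_rows(test_idx)
    grid = grid if grid is not None else {"max_depth": [3], "n_estimators": [100]}
    model = fit_gbt(train_tab, y[train_idx], grid=grid, seed=seed, features=selected)
    scores = predict_risk(model, test_tab)
    evals = {"overall": evaluate_auroc(scores, y[test_idx], n_boot=n_boot, seed=seed)}
    sex = test_tab.data[sex_column].to_numpy() if sex_column in test_tab.data else None
    if sex is not None:
        for label, val in (("male", 1.0), ("female", 0.0)):
            try:
                evals[label] = evaluate_auroc(
                    scores, y[test_idx], n_boot=n_boot, seed=seed,
                    stratum_mask=sex == val, stratum=label,
                )
            except ValueError:
                pass  # one-class stratum: skip rather than fail the build
    base_risk = float(np.mean(predict_risk(model, train_tab)))
    cycles = ()
    if table.cycle is not None:
        cycles = tuple(sorted(np.unique(np.asarray(table.cycle)[train_idx]).tolist()))
    score = RiskScoreModel(model, selected, tier.name, evals, base_risk, cycles)
    # keep a background for explanations
    score.background = train_tab.values(selected)[
        np.random.default_rng(seed).choice(
            len(train_idx), size=min(len(train_idx), 128), replace=False
        )
    ]
    return score


def temporal_validate(
    score: RiskScoreModel,
    table: FeatureTable,
    labels: np.ndarray | pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvaluationResult:
    """Bootstrap AUROC on subjects from enrollment cycles strictly later
    than every training cycle; rejects overlapping cycles."""
    if table.cycle is None:
        raise ValueError("temporal validation requires a cycle column")
    if not score.train_cycles:
        raise ValueError("risk score lacks a training-cycle record")
    cyc = np.asarray(table.cycle)
    overlap = set(np.unique(cyc).tolist()) & set(score.train_cycles)
    if overlap:
        raise ValueError(f"validation cycles overlap training cycles: {sorted(overlap)}")
    scores = predict_risk(score.model, table)
    ev = evaluate_auroc(scores, np.asarray(labels).astype(int), n_boot=n_boot, seed=seed)
    score.evaluations["temporal"] = ev
    return ev


def explain_individual(
    score: RiskScoreModel,
    subject: pd.Series | pd.DataFrame,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> IndividualExplanation:
    """Per-feature probability-space contributions for one subject.

    Log-odds attributions are rescaled proportionally by
    ``(risk - base_risk) / sum(phi)`` so that the base value (mean risk
    score) plus the contributions reconstructs the subject's risk score
    exactly; a zero attribution sum yields zero contributions.
    """
    if isinstance(subject, pd.Series):
        row = subject.to_frame().T
    else:
        row = subject
    missing = [f for f in score.features if f not in row.columns]
    if missing:
        raise KeyError(f"subject lacks model features: {missing}")
    row = row[score.features].astype(float)
    bg = background if background is not None else getattr(score, "background", None)
    attr = attribute(score.model, row, background=bg, seed=seed)
    phi = attr.phi.iloc[0]
    risk = float(predict_risk(score.model, row)[0])
    base = score.base_risk
    total = float(phi.sum())
    if abs(total) < 1e-12:
        contrib = phi * 0.0
    else:
        contrib = phi * ((risk - base) / total)
    return IndividualExplanation(
        subject_id=row.index[0],
        risk_score=risk,
        base_value=base,
        contributions=contrib,
        feature_values=row.iloc[0],
    )


def waterfall_text(expl: IndividualExplanation, n: int = 10) -> str:
    """Plain-text waterfall of the largest probability-space contributions."""
    lines = [
        f"subject {expl.subject_id}: risk score {expl.risk_score:.4f} "
        f"(base {expl.base_value:.4f})"
    ]
    for feat, c in expl.top_features(n).items():
        v = expl.feature_values[feat]
        arrow = "raises" if c > 0 else "lowers"
        lines.append(f"  {feat} = {v:.3g}: {arrow} risk by {abs(c):.4f}")
    return "\n".join(lines)
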