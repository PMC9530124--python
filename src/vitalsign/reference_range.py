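"""Relative-risk curves and reference-interval auditing.

A laboratory reference interval (RI) is conventionally the central 95% of
a healthy reference population, a definition blind to outcome risk.  The
audit here asks a trained mortality model how risk actually varies over a
feature's range: the relative risk curve r(v) substitutes value v into
every test subject, averages the predicted event probability, and divides
by the unmodified cohort-mean prediction, so r = 1 is average risk.

The relative risk percentage (RRP) then scores an interval:

    RRP = 100 * (max_{v in RI} r(v) - 1) / (max_v r(v) - 1)

RRP is 100% exactly when the interval contains the global risk maximum
(the strongest indictment of an interval meant to describe "normal"),
negative when risk inside the interval stays below the cohort average,
and 0 by convention for a flat curve.  Being a ratio of relative risks,
it is invariant to rescaling all predictions by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .models import TrainedModel, predict_risk


@dataclass
class RelativeRiskCurve:
    feature: str
    grid: np.ndarray
    r: np.ndarray  # relative risk at each grid value
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("empty grid")
        if np.any(self.r <= 0):
            raise ValueError("relative risk must be positive")


@dataclass(frozen=True)
class ReferenceInterval:
    feature: str
    low: float
    high: float
    sex: str | None = None  # None, "male" or "female"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("reference interval requires low < high")


@dataclass
class RRPResult:
    feature: str
    rrp: float  # signed percentage, capped at 100
    horizon: str | None = None
    sex: str | None = None
    suboptimal: bool = False


def relative_risk_curve(
    model: TrainedModel | Callable[[pd.DataFrame], np.ndarray],
    table: FeatureTable | pd.DataFrame,
    feature: str,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    percentile_range: tuple[float, float] = (0.5, 99.5),
) -> RelativeRiskCurve:
    """Partial-dependence relative risk of one feature.

    The grid defaults to ``n_grid`` points at empirical percentiles
    0.5-99.5 of the observed values (tail-robust).  ``model`` may be a
    :class:`TrainedModel` or any callable mapping a DataFrame to
    predicted probabilities.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    if isinstance(model, TrainedModel):
        if feature not in model.features:
            raise KeyError(f"feature {feature!r} not in model")
        predict = lambda d: predict_risk(model, d)  # noqa: E731
    else:
        predict = model
    obs = df[feature].to_numpy(dtype=float)
    obs_ok = obs[~np.isnan(obs)]
    if grid is None:
        lo, hi = percentile_range
        grid = np.unique(np.percentile(obs_ok, np.linspace(lo, hi, n_grid)))
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    base = float(np.mean(predict(df)))
    r = np.empty(grid.size)
    work = df.copy()
    for k, v in enumerate(grid):
        work[feature] = v
        r[k] = float(np.mean(predict(work))) / base
    counts, edges = np.histogram(obs_ok, bins=30)
    return RelativeRiskCurve(feature, grid, r, counts, edges)


def rrp(
    curve: RelativeRiskCurve,
    ri: ReferenceInterval,
    flat_eps: float = 1e-6,
    flag_threshold: float = 50.0,
    horizon: str | None = None,
) -> RRPResult:
    """Score a reference interval against a relative-risk curve."""
    if ri.feature != curve.feature:
        raise ValueError("interval/curve feature mismatch")
    inside = (curve.grid >= ri.low) & (curve.grid <= ri.high)
    if not inside.any():
        raise ValueError(
            f"no grid point of {curve.feature!r} inside [{ri.low}, {ri.high}]"
        )
    peak_all = float(curve.r.max()) - 1.0
    if peak_all < flat_eps:
        value = 0.0
    else:
        peak_in = float(curve.r[inside].max()) - 1.0
        value = 100.0 * peak_in / peak_all
    return RRPResult(
        curve.feature, value, horizon, ri.sex, suboptimal=value > flag_threshold
    )


def audit_intervals(
    models: Mapping[str, TrainedModel],
    table: FeatureTable,
    intervals: Sequence[ReferenceInterval],
    horizons: Sequence[str] | None = None,
    sex_column: str = "sex",
    sex_coding: Mapping[str, float] = {"male": 1.0, "female": 0.0},
    flag_threshold: float = 50.0,
    n_grid: int = 100,
) -> pd.DataFrame:
    """RRP report shaped feature (x sex stratum) by horizon.

    ``models`` maps horizon tags (e.g. ``"5y"``) to trained models; a
    missing horizon simply omits that column.  Sex-stratified intervals
    are evaluated on the matching subject stratum.  The evaluation grid
    is the percentile grid extended with points spanning the interval, so
    an interval in a sparse tail is always sampled.
    """
    tags = list(horizons) if horizons is not None else list(models)
    rows = []
    for ri in intervals:
        row: dict[str, object] = {
            "feature": ri.feature,
            "sex": ri.sex,
            "low": ri.low,
            "high": ri.high,
        }
        for tag in tags:
            if tag not in models:
                continue
            model = models[tag]
            tab = table
            if ri.sex is not None:
                mask = table.data[sex_column].to_numpy() == sex_coding[ri.sex]
                tab = table.subset_rows(np.flatnonzero(mask))
            obs = tab.data[ri.feature].to_numpy(dtype=float)
            obs = obs[~np.isnan(obs)]
            grid = np.union1d(
                np.percentile(obs, np.linspace(0.5, 99.5, n_grid)),
                np.linspace(ri.low, ri.high, 11),
            )
            curve = relative_risk_curve(model, tab, ri.feature, grid=grid)
            res = rrp(curve, ri, flag_threshold=flag_threshold, horizon=tag)
            row[f"rrp_{tag}"] = res.rrp
            row[f"suboptimal_{tag}"] = res.suboptimal
        rows.append(row)
    return pd.DataFrame(rows)
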