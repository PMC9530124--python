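"""Core data containers shared across the pipeline.

The central object is :class:`FeatureTable`, a thin wrapper around a pandas
DataFrame of subjects x features that additionally carries a role for every
feature (demographic / examination / laboratory / questionnaire) and an
ordinal enrollment-cycle vector used for temporal validation splits.
Missing values are encoded as NaN in the DataFrame itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("demographic", "examination", "laboratory", "questionnaire")


@dataclass
class FeatureTable:
    """Subjects x named features with missingness and per-feature roles.

    Parameters
    ----------
    data:
        DataFrame of numeric feature values; NaN marks a missing entry.
        The index holds subject ids.
    roles:
        Mapping of every feature name to one of :data:`ROLES`.
    cycle:
        Optional ordinal enrollment period per subject (aligned with
        ``data.index``); required for temporal splits.
    """

    data: pd.DataFrame
    roles: Mapping[str, str]
    cycle: np.ndarray | None = None

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        missing_roles = [c for c in cols if c not in self.roles]
        if missing_roles:
            raise ValueError(f"features without a role: {missing_roles}")
        bad = {c: r for c, r in self.roles.items() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown roles: {bad}")
        if self.cycle is not None:
            self.cycle = np.asarray(self.cycle)
            if len(self.cycle) != len(self.data):
                raise ValueError("cycle length does not match table")

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def values(self, features: Sequence[str] | None = None) -> np.ndarray:
        """Feature matrix as float64 with NaN for missing entries."""
        cols = list(features) if features is not None else self.features
        absent = [c for c in cols if c not in self.data.columns]
        if absent:
            raise KeyError(f"features not in table: {absent}")
        return self.data[cols].to_numpy(dtype=np.float64)

    def features_by_role(self, roles: Sequence[str]) -> list[str]:
        want = set(roles)
        return [c for c in self.features if self.roles[c] in want]

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        cyc = self.cycle[idx] if self.cycle is not None else None
        return FeatureTable(self.data.iloc[idx].copy(), dict(self.roles), cyc)

    def subset_features(self, features: Sequence[str]) -> "FeatureTable":
        roles = {c: self.roles[c] for c in features}
        return FeatureTable(self.data[list(features)].copy(), roles, self.cycle)

    def missingness(self) -> pd.Series:
        """Per-feature fraction of missing entries."""
        return self.data.isna().mean()


@dataclass
class EvaluationResult:
    """AUROC point estimate with a percentile bootstrap interval."""

    auroc: float
    n_boot: int
    ci_low: float
    ci_high: float
    replicates: np.ndarray = field(repr=False)
    stratum: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auroc <= 1.0:
            raise ValueError("AUROC outside [0, 1]")
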