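"""Shared fixtures: one session-scoped bench cohort and trained model.

The bench cohort is a default-scale (8,000-subject) draw of the synthetic spec
(planted U-shape, threshold, monotone and interaction effects, a
redundant anthropometric group and noise features); fitting the tree
model once per session keeps the suite fast.
"""

import numpy as np
import pandas as pd
import pytest

import vitalsign as vs

SMALL_GRID = {"max_depth": [3], "n_estimators": [100], "learning_rate": [0.1]}


@pytest.fixture(scope="session")
def bench_spec():
    return vs.default_cohort_spec(n_subjects=8000, n_noise_features=5, seed=7)


@pytest.fixture(scope="session")
def bench(bench_spec):
    table, labels, truth = vs.generate_cohort(bench_spec)
    return table, labels, truth


@pytest.fixture(scope="session")
def bench_split(bench):
    table, _, _ = bench
    return vs.split_cohort(table, "random_80_20", seed=7)


@pytest.fixture(scope="session")
def bench_gbt(bench, bench_split):
    table, labels, _ = bench
    train_idx, _ = bench_split
    y = labels["death_5y"].to_numpy()
    return vs.fit_gbt(
        table.subset_rows(train_idx), y[train_idx], grid=SMALL_GRID, seed=7
    )


def make_table(X: np.ndarray, prefix: str = "x", role: str = "laboratory"):
    cols = [f"{prefix}{i}" for i in range(X.shape[1])]
    return vs.FeatureTable(pd.DataFrame(X, columns=cols), {c: role for c in cols})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
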