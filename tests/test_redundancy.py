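"""Supervised distance: arithmetic, limits, clustering, selection."""

import numpy as np
import pytest

import vitalsign as vs
from vitalsign.redundancy import r2_from_predictions, _PairCache, min_pairwise_distance
from conftest import SMALL_GRID, make_table


@pytest.fixture(scope="module")
def signal_noise_data():
    rng = np.random.default_rng(12)
    n = 3000
    x = rng.normal(size=n)
    data = np.column_stack(
        [
            x,  # signal
            x + 0.02 * rng.normal(size=n),  # near copy
            np.exp(x),  # monotone transform
            rng.normal(size=n),  # independent noise
        ]
    )
    y = (rng.random(n) < 1 / (1 + np.exp(-(2 * x - 1.5)))).astype(int)
    return make_table(data), y


class TestArithmetic:
    def test_r2_formula_direct_cases(self):
        p = np.array([0.1, 0.4, 0.7, 0.9])
        assert r2_from_predictions(p, p) == 1.0
        # residual MSE exceeding var clips to exactly zero
        bad = 1.0 - p
        assert r2_from_predictions(p, bad) == 0.0
        # constant prediction vector: defined result 0 (no label information)
        assert r2_from_predictions(np.full(4, 0.3), p) == 0.0

    def test_r2_formula_matches_manual_arithmetic(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = p + 0.1 * rng.normal(size=50)
        manual = max(0.0, 1.0 - np.mean((p - q) ** 2 / np.var(p)))
        assert r2_from_predictions(p, q) == pytest.approx(manual, abs=0)


class TestDistanceLimits:
    def test_self_distance_near_zero(self, signal_noise_data):
        table, y = signal_noise_data
        x = table.data["x0"].to_numpy()
        assert vs.supervised_distance(x, x, y) < 0.01

    def test_identity_r2_high(self, signal_noise_data):
        table, y = signal_noise_data
        x = table.data["x0"].to_numpy()
        assert vs.supervised_r2(x, x, y) >= 0.99

    def test_monotone_transform_is_redundant(self, signal_noise_data):
        table, y = signal_noise_data
        d = vs.supervised_distance(
            table.data["x0"].to_numpy(), table.data["x2"].to_numpy(), y
        )
        assert d < 0.1

    def test_independent_noise_not_redundant(self, signal_noise_data):
        table, y = signal_noise_data
        d = vs.supervised_distance(
            table.data["x0"].to_numpy(), table.data["x3"].to_numpy(), y
        )
        assert d > 0.9

    def test_uninformative_feature_distance_is_one(self, signal_noise_data):
        """var(Prediction_i) ~ 0 direction forces distance 1."""
        table, y = signal_noise_data
        const = np.zeros(table.n_subjects)
        d = vs.supervised_distance(const, table.data["x0"].to_numpy(), y)
        assert d == 1.0


class TestDistanceMatrix:
    def test_matches_pairwise_calls_and_symmetry(self, signal_noise_data):
        table, y = signal_noise_data
        dm = vs.distance_matrix(table, y, keep_predictions=True)
        assert np.abs(dm.values - dm.values.T).max() == 0.0
        assert np.all(np.diag(dm.values) == 0.0)
        assert np.all((dm.values >= 0) & (dm.values <= 1 + 1e-9))
        d01 = vs.supervised_distance(
            table.data["x0"].to_numpy(), table.data["x1"].to_numpy(), y
        )
        assert dm.lookup("x0", "x1") == pytest.approx(d01, abs=1e-12)

    def test_stored_predictions_rederive_r2_exactly(self, signal_noise_data):
        table, y = signal_noise_data
        dm = vs.distance_matrix(table, y, keep_predictions=True)
        for a, fi in enumerate(dm.features):
            for b, fj in enumerate(dm.features):
                if a == b:
                    continue
                re_r2 = r2_from_predictions(
                    dm.prediction_i[fi], dm.prediction_ij[(fi, fj)]
                )
                assert re_r2 == dm.r2[a, b]

    def test_single_feature_rejected(self, signal_noise_data):
        table, y = signal_noise_data
        with pytest.raises(ValueError):
            vs.distance_matrix(table.subset_features(["x0"]), y)


class TestClustering:
    def test_k_extremes(self, signal_noise_data):
        table, y = signal_noise_data
        dm = vs.distance_matrix(table, y)
        singletons = vs.cluster_features(dm, k=4)
        assert len(set(singletons.assignment.values())) == 4
        one = vs.cluster_features(dm, k=1)
        assert len(set(one.assignment.values())) == 1
        with pytest.raises(ValueError):
            vs.cluster_features(dm, k=5)

    def test_redundant_features_cluster_together(self, signal_noise_data):
        table, y = signal_noise_data
        dm = vs.distance_matrix(table, y)
        clust = vs.cluster_features(dm, k=2)
        a = clust.assignment
        assert a["x0"] == a["x1"] == a["x2"]
        assert a["x3"] != a["x0"]

    def test_complete_linkage_heights_non_decreasing(self, signal_noise_data):
        table, y = signal_noise_data
        dm = vs.distance_matrix(table, y)
        clust = vs.cluster_features(dm, k=2)
        heights = clust.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_planted_group_recovered_on_bench(self, bench, bench_split):
        table, labels, truth = bench
        train_idx, _ = bench_split
        y = labels["death_5y"].to_numpy()
        members = sorted(truth.redundancy_assignment)
        feats = members + ["uric_acid", "rdw", "noise_lab_01", "noise_lab_02"]
        dm = vs.distance_matrix(table, y, train_idx, features=feats, seed=1)
        within = [
            dm.lookup(a, b) for i, a in enumerate(members) for b in members[i + 1:]
        ]
        others = [f for f in feats if f not in members]
        between = [dm.lookup(a, b) for a in members for b in others]
        assert np.mean(within) < np.mean(between)
        clust = vs.cluster_features(dm, k=5)
        assert len({clust.assignment[m] for m in members}) == 1


class TestSelection:
    @pytest.fixture(scope="class")
    def trajectory(self, bench, bench_split):
        table, labels, _ = bench
        train_idx, test_idx = bench_split
        y = labels["death_5y"].to_numpy()
        return vs.sd_feature_selection(
            table, y, train_idx, test_idx, step=4, grid=SMALL_GRID,
            n_boot=100, seed=3,
        )

    def test_anchors_always_present(self, trajectory):
        for rec in trajectory:
            assert "age" in rec.features and "sex" in rec.features

    def test_sizes_shrink_and_terminate(self, trajectory):
        sizes = [len(r.features) for r in trajectory]
        assert sizes[0] > sizes[-1]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_redundancy_decreases_as_set_shrinks(self, trajectory):
        """Smaller selected sets show larger minimum supervised distance
        (negative rank correlation of size with min distance)."""
        from scipy.stats import spearmanr

        sizes = [len(r.features) for r in trajectory]
        mins = [r.min_supervised_distance for r in trajectory]
        rho, _ = spearmanr(sizes, mins)
        assert rho < 0

    def test_at_most_one_group_member_survives(self, trajectory, bench):
        _, _, truth = bench
        members = set(truth.redundancy_assignment)
        # after the first shrinking iteration the redundant group collapses
        for rec in trajectory[1:]:
            assert len(members & set(rec.features)) <= 1

    def test_missing_anchor_rejected(self, bench, bench_split):
        table, labels, _ = bench
        train_idx, test_idx = bench_split
        with pytest.raises(ValueError, match="absent"):
            vs.sd_feature_selection(
                table, labels["death_5y"].to_numpy(), train_idx, test_idx,
                always_keep=("age", "nope"),
            )


def test_credit_splitting_mitigated_by_selection():
    """Two near-copies of one signal split importance in the full model;
    the selected low-redundancy set keeps exactly one copy whose refit
    importance exceeds either copy's in the full model."""
    rng = np.random.default_rng(21)
    n = 3000
    sig = rng.normal(size=n)
    X = np.column_stack(
        [
            rng.uniform(18, 85, n),  # "age" anchor stand-in
            rng.integers(0, 2, n).astype(float),  # "sex" anchor stand-in
            sig,
            sig + 0.03 * rng.normal(size=n),  # near copy
            rng.normal(size=n),
        ]
    )
    import pandas as pd

    table = vs.FeatureTable(
        pd.DataFrame(X, columns=["age", "sex", "copy_a", "copy_b", "noise"]),
        {c: "laboratory" for c in ["copy_a", "copy_b", "noise"]}
        | {"age": "demographic", "sex": "demographic"},
    )
    logit = -2.0 + 1.2 * sig + 0.01 * (X[:, 0] - 50) / 20
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    train, test = vs.split_cohort(table, seed=0)
    traj = vs.sd_feature_selection(
        table, y, train, test, step=2, grid=SMALL_GRID, n_boot=50, seed=0
    )
    full_model = vs.fit_gbt(table.subset_rows(train), y[train], grid=SMALL_GRID)
    full_rank = vs.importance(
        vs.attribute(full_model, table.subset_rows(train), max_background=64, seed=0)
    )
    full_vals = dict(zip(full_rank.features, full_rank.values))
    final = traj[-1].features
    kept = [f for f in final if f in ("copy_a", "copy_b")]
    assert len(kept) == 1
    refit = vs.fit_gbt(
        table.subset_rows(train), y[train], grid=SMALL_GRID, features=final
    )
    refit_rank = vs.importance(
        vs.attribute(refit, table.subset_rows(train).subset_features(final),
                     max_background=64, seed=0)
    )
    refit_vals = dict(zip(refit_rank.features, refit_rank.values))
    assert refit_vals[kept[0]] > max(full_vals["copy_a"], full_vals["copy_b"])
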