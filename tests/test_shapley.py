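"""Attribution contracts: additivity, the enumeration oracle, interaction
decomposition, importance ranking and ranking comparison."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from xgboost import XGBClassifier, XGBRegressor

import vitalsign as vs
from vitalsign.models import TrainedModel
from vitalsign.shapley import _resolve_background


def _random_small_model(seed, n=150, d=3, depth=2, trees=4, nan_frac=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    X[rng.random(X.shape) < nan_frac] = np.nan
    coef = rng.normal(size=d)
    y = (np.nansum(X * coef, axis=1) + 0.3 * rng.normal(size=n) > 0).astype(int)
    if y.min() == y.max():
        y[: n // 2] = 1 - y[0]
    m = XGBClassifier(
        n_estimators=trees, max_depth=depth, learning_rate=0.5, n_jobs=1,
        random_state=seed, eval_metric="logloss",
    )
    m.fit(X, y)
    feats = [f"x{i}" for i in range(d)]
    return TrainedModel(m, feats), pd.DataFrame(X, columns=feats)


def brute_force_interactions(model, x, background):
    """Shapley interaction index by direct subset enumeration."""
    margin = lambda A: model.model.predict(A, output_margin=True)  # noqa: E731
    bg = np.asarray(background, dtype=float)
    d = x.size
    vals = {}
    for r in range(d + 1):
        for S in combinations(range(d), r):
            A = bg.copy()
            A[:, list(S)] = x[list(S)]
            vals[S] = float(np.mean(margin(A)))

    def v(S):
        return vals[tuple(sorted(S))]

    phi_ij = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            if i == j:
                continue
            others = [k for k in range(d) if k not in (i, j)]
            for r in range(d - 1):
                coef = (
                    math.factorial(r) * math.factorial(d - r - 2)
                    / (2 * math.factorial(d - 1))
                )
                for S in combinations(others, r):
                    delta = (
                        v(S + (i, j)) - v(S + (i,)) - v(S + (j,)) + v(S)
                    )
                    phi_ij[i, j] += coef * delta
    phi = vs.brute_force_shapley(model, x, bg)
    np.fill_diagonal(phi_ij, phi - phi_ij.sum(axis=1))
    return phi_ij


class TestAdditivity:
    def test_constant_model_has_zero_attributions(self, rng):
        X = rng.normal(size=(100, 3))
        y = rng.integers(0, 2, size=100)
        m = XGBClassifier(n_estimators=3, max_depth=3, gamma=1e9, n_jobs=1,
                          eval_metric="logloss")
        m.fit(X, y)
        tm = TrainedModel(m, ["x0", "x1", "x2"])
        attr = vs.attribute(tm, pd.DataFrame(X, columns=tm.features), seed=0)
        assert np.abs(attr.phi.to_numpy()).max() < 1e-12
        assert attr.base_value == pytest.approx(m.predict(X, output_margin=True)[0], abs=1e-6)

    def test_additivity_on_bench_cohort(self, bench, bench_gbt):
        """base + sum(phi) reproduces the model margin, with missing data."""
        table, _, _ = bench
        sub = table.subset_rows(np.arange(300))
        attr = vs.attribute(bench_gbt, sub, max_background=64, seed=0)
        margin = bench_gbt.margin(sub)
        err = np.abs(attr.base_value + attr.phi.sum(axis=1).to_numpy() - margin)
        assert (err < 1e-6 * (1 + np.abs(margin))).all()

    def test_feature_mismatch_rejected(self, bench, bench_gbt):
        table, _, _ = bench
        with pytest.raises(KeyError):
            vs.attribute(bench_gbt, table.data.drop(columns=["rdw"]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_attribute_matches_enumeration(self, seed):
        model, X = _random_small_model(seed, d=3 + seed % 2, depth=2 + seed % 2,
                                       trees=3 + seed % 3)
        bg = _resolve_background(model, X, None, 25, seed)
        attr = vs.attribute(model, X.iloc[:6], background=bg, seed=seed)
        for i in range(6):
            exact = vs.brute_force_shapley(model, X.iloc[i].to_numpy(), bg)
            assert np.abs(attr.phi.iloc[i].to_numpy() - exact).max() < 1e-6

    def test_symmetry_axiom(self):
        """A model depending symmetrically on two features with an
        exchangeable background gives phi0 = phi1."""
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(50, 2))
        bg = np.vstack([bg, bg[:, ::-1]])  # exchangeable by construction
        f = lambda A: A[:, 0] + A[:, 1]  # noqa: E731
        phi = vs.brute_force_shapley(f, np.array([1.3, 1.3]), bg)
        assert phi[0] == pytest.approx(phi[1], abs=1e-9)

    def test_null_player_axiom(self, rng):
        """A feature the trees never split on gets exactly zero."""
        X = rng.normal(size=(300, 3))
        y = (X[:, 0] > 0).astype(int)  # only x0 informative
        m = XGBClassifier(n_estimators=5, max_depth=1, n_jobs=1, eval_metric="logloss")
        m.fit(X, y)
        used = {f for f in m.get_booster().get_score(importance_type="weight")}
        tm = TrainedModel(m, ["x0", "x1", "x2"])
        phi = vs.brute_force_shapley(tm, X[0], X[:40])
        for k, name in enumerate(["f0", "f1", "f2"]):
            if name not in used:
                assert phi[k] == 0.0


class TestInteractions:
    def test_additive_model_has_no_interactions(self, rng):
        X = rng.normal(size=(600, 2))
        y_cont = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2
        m = XGBRegressor(n_estimators=30, max_depth=1, n_jobs=1)  # stumps: additive
        m.fit(X, y_cont)
        tm = TrainedModel(m, ["a", "b"])
        tm.margin = lambda t: m.predict(t[["a", "b"]].to_numpy())  # regression margin
        it = vs.interactions(tm, pd.DataFrame(X[:40], columns=["a", "b"]),
                             background=X[:40], seed=0)
        off = it.values[:, 0, 1]
        assert np.abs(off).max() < 1e-9

    def test_row_sums_reproduce_phi(self, bench, bench_gbt):
        table, _, _ = bench
        sub = table.subset_rows(np.arange(40))
        bg = _resolve_background(bench_gbt, sub, None, 32, 0)
        it = vs.interactions(bench_gbt, sub, background=bg, seed=0)
        attr = vs.attribute(bench_gbt, sub, background=bg, seed=0)
        assert np.abs(it.phi() - attr.phi.to_numpy()).max() < 1e-6
        assert np.abs(it.values - it.values.transpose(0, 2, 1)).max() < 1e-9

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        model, X = _random_small_model(seed + 100, d=3, depth=2, trees=3)
        bg = X.to_numpy()[:20]
        it = vs.interactions(model, X.iloc[:3], background=bg, seed=seed)
        for i in range(3):
            exact = brute_force_interactions(model, X.iloc[i].to_numpy(), bg)
            # oracle precision limited by the model's float32 margin output
            assert np.abs(it.values[i] - exact).max() < 2e-7


def test_consistency_under_added_dependence():
    """Strictly deepening the model's dependence on a feature never
    lowers its mean absolute attribution."""
    rng = np.random.default_rng(9)
    X = rng.integers(0, 2, size=(800, 3)).astype(float)
    f1 = X[:, 0] + 2 * X[:, 1]
    f2 = f1 + 1.5 * X[:, 2]  # added dependence on x2
    ms = []
    for target in (f1, f2):
        m = XGBRegressor(n_estimators=60, max_depth=3, learning_rate=0.5, n_jobs=1)
        m.fit(X, target)
        ms.append(TrainedModel(m, ["x0", "x1", "x2"]))
    bg = X[:64]
    phis = []
    for tm in ms:
        phi = np.array([vs.brute_force_shapley(tm, X[i], bg) for i in range(30)])
        phis.append(np.abs(phi).mean(axis=0))
    assert phis[1][2] >= phis[0][2] - 1e-9


class TestImportance:
    def test_zero_feature_ranked_last_and_ties_lexicographic(self):
        phi = pd.DataFrame(
            {"b": [1.0, -1.0], "a": [1.0, 1.0], "z": [0.0, 0.0], "c": [1.0, 1.0]}
        )
        rank = vs.importance(vs.AttributionSet(phi, 0.0))
        assert rank.features[-1] == "z"
        assert rank.features[:3] == ["a", "b", "c"]  # equal means, name order

    def test_subject_order_invariance(self, bench, bench_gbt):
        table, _, _ = bench
        sub = table.subset_rows(np.arange(150))
        bg = _resolve_background(bench_gbt, sub, None, 32, 0)
        a = vs.importance(vs.attribute(bench_gbt, sub, background=bg))
        perm = np.random.default_rng(1).permutation(150)
        b = vs.importance(vs.attribute(bench_gbt, sub.subset_rows(perm), background=bg))
        assert a.features == b.features

    def test_signal_outranks_noise_on_bench(self, bench, bench_gbt, bench_split):
        table, _, _ = bench
        train_idx, _ = bench_split
        train = table.subset_rows(train_idx)
        rank = vs.importance(vs.attribute(bench_gbt, train, max_background=64, seed=0))
        noise = [f for f in table.features if f.startswith("noise_")]
        strong = ["age", "uric_acid", "rdw", "urine_albumin"]
        worst_strong = max(rank.features.index(f) for f in strong)
        best_noise = min(rank.features.index(f) for f in noise)
        assert worst_strong < best_noise


class TestCompareRankings:
    def test_identical_rankings(self):
        uni = [f"f{i}" for i in range(30)]
        res = vs.compare_rankings(uni, uni, uni, k=10)
        assert res["overlap"] == 10
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_published_overlap_example(self):
        """Two top-20 sets over a 51-feature universe sharing 14 members:
        two-sided Fisher exact p rounds to 0.0004."""
        uni = [f"f{i}" for i in range(51)]
        a = uni
        b = uni[:14] + uni[20:26] + uni[14:20] + uni[26:]
        res = vs.compare_rankings(a, b, uni, k=20)
        assert res["overlap"] == 14
        assert res["fisher_p"] == pytest.approx(0.0004, abs=5e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_fisher_p_equals_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        uni = [f"f{i}" for i in range(40)]
        b = list(rng.permutation(uni))
        k = 10
        res = vs.compare_rankings(uni, b, uni, k=k)
        # two-sided exact p: sum of hypergeometric point masses <= P(observed)
        hg = hypergeom(40, k, k)
        p_obs = hg.pmf(res["overlap"])
        expected = sum(
            hg.pmf(x) for x in range(0, k + 1) if hg.pmf(x) <= p_obs * (1 + 1e-9)
        )
        assert res["fisher_p"] == pytest.approx(expected, rel=1e-6)

    def test_k_larger_than_universe_rejected(self):
        uni = ["a", "b"]
        with pytest.raises(ValueError):
            vs.compare_rankings(uni, uni, uni, k=3)
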