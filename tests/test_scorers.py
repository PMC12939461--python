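"""Scorer contracts: oracle values, determinism, univariate locality."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from rankstab import (
    SCORER_IDS,
    ScorerConfig,
    drop_features,
    get_scorer,
    register_scorer,
    score_forest_impurity,
    score_gbt_gain,
    score_lasso,
    score_ols,
    score_pca_loading_sum,
    score_spearman,
    score_variance,
)
from rankstab.scorers import _REGISTRY

from conftest import make_table, random_table

DETERMINISTIC = ("ols_abs_coef", "lasso_abs_coef", "pca_loading_sum", "variance", "spearman_abs")


class TestOLS:
    def test_simple_regression_slope(self, fixtures):
        scores = score_ols(fixtures["ols_example"]).scores
        assert scores["x_ols"] == pytest.approx(0.4, abs=1e-9)

    def test_feature_identical_to_outcome(self):
        y = np.array([0, 1, 0, 1])
        table = make_table(y.reshape(-1, 1).astype(float), ["x"], y)
        assert score_ols(table).scores["x"] == pytest.approx(1.0, abs=1e-9)

    def test_constant_feature_scores_zero(self):
        y = np.array([0, 0, 1, 1])
        table = make_table(
            np.column_stack([np.ones(4), [0.0, 1.0, 2.0, 3.0]]), ["const", "x"], y
        )
        assert score_ols(table).scores["const"] == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficient_minimum_norm(self, fixtures):
        result = score_ols(fixtures["wide"])
        vals = np.array(list(result.scores.values()))
        assert np.all(np.isfinite(vals)) and np.all(vals >= 0)
        assert result.metadata["solution"] == "minimum_norm_lstsq"


class TestLasso:
    def test_noise_feature_shrunk_to_zero(self):
        rng = np.random.default_rng(3)
        y = np.tile([0, 1], 20)
        signal = y + 0.01 * rng.standard_normal(40)
        noise = rng.standard_normal(40)
        table = make_table(np.column_stack([signal, noise]), ["s", "n"], y)
        scores = score_lasso(table, ScorerConfig(lasso_alpha=0.2)).scores
        assert scores["n"] == 0.0

    def test_alpha_to_zero_approaches_ols(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 3))
        y = (X[:, 0] > 0).astype(int)
        table = make_table(X, outcome=y)
        ols = score_ols(table).scores
        lasso = score_lasso(table, ScorerConfig(lasso_alpha=1e-8, lasso_max_iter=500_000)).scores
        for f in ols:
            assert lasso[f] == pytest.approx(ols[f], abs=1e-3)

    def test_duplicated_column_coefficients_split(self):
        rng = np.random.default_rng(7)
        n = 60
        y = np.zeros(n, dtype=int)
        y[: n // 2] = 1
        info = y + 0.1 * rng.standard_normal(n)
        single = make_table(info.reshape(-1, 1), ["a"], y)
        pair = make_table(np.column_stack([info, info]), ["a", "b"], y)
        cfg = ScorerConfig(lasso_alpha=0.01)
        solo = score_lasso(single, cfg).scores["a"]
        dup = score_lasso(pair, cfg).scores
        assert dup["a"] + dup["b"] == pytest.approx(solo, abs=1e-6)

    def test_convergence_recorded(self):
        rng = np.random.default_rng(9)
        table = make_table(rng.standard_normal((20, 5)))
        result = score_lasso(table, ScorerConfig(lasso_alpha=0.01, lasso_max_iter=10_000))
        assert result.metadata["converged"] is True


class TestForest:
    def test_noise_scores_stay_near_uniform(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 20))
        y = np.zeros(200, dtype=int)
        y[rng.permutation(200)[:60]] = 1
        table = make_table(X, outcome=y)
        for seed in range(5):
            scores = np.array(
                list(score_forest_impurity(table, ScorerConfig(seed=seed)).scores.values())
            )
            assert scores.max() <= 3 * scores.mean()

    def test_separating_feature_attains_maximum(self):
        rng = np.random.default_rng(0)
        y = np.zeros(200, dtype=int)
        y[rng.permutation(200)[:70]] = 1
        X = np.column_stack([y.astype(float)] + [rng.standard_normal(200) for _ in range(9)])
        table = make_table(X, ["sep"] + [f"n{i}" for i in range(9)], y)
        scores = score_forest_impurity(table, ScorerConfig(seed=0)).scores
        assert max(scores, key=scores.get) == "sep"

    def test_scores_sum_to_one(self, small_synthetic):
        table, _ = small_synthetic
        scores = np.array(list(score_forest_impurity(table).scores.values()))
        assert scores.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_class_outcome_rejected(self):
        table = make_table(np.random.default_rng(0).standard_normal((10, 3)),
                           outcome=np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="both outcome classes"):
            score_forest_impurity(table)


class TestGBT:
    def test_unsplit_feature_scores_zero(self):
        rng = np.random.default_rng(1)
        y = np.zeros(100, dtype=int)
        y[:40] = 1
        X = np.column_stack([y.astype(float), np.ones(100)])
        table = make_table(X, ["sep", "const"], y)
        scores = score_gbt_gain(table).scores
        assert scores["const"] == 0.0

    def test_separating_feature_is_top(self):
        rng = np.random.default_rng(2)
        y = np.zeros(200, dtype=int)
        y[rng.permutation(200)[:60]] = 1
        X = np.column_stack([y.astype(float)] + [rng.standard_normal(200) for _ in range(9)])
        table = make_table(X, ["sep"] + [f"n{i}" for i in range(9)], y)
        scores = score_gbt_gain(table).scores
        assert max(scores, key=scores.get) == "sep"

    def test_rankings_identical_across_seeds(self, small_synthetic):
        table, _ = small_synthetic
        rankings = []
        for seed in (0, 1, 42):
            scores = score_gbt_gain(table, ScorerConfig(seed=seed)).scores
            rankings.append(sorted(scores, key=lambda f: (-scores[f], table.column_order[f])))
        assert rankings[0] == rankings[1] == rankings[2]


class TestPCA:
    def test_uncorrelated_axes_score_one_each(self, fixtures):
        scores = score_pca_loading_sum(fixtures["pca_uncorrelated"]).scores
        assert scores["wide_axis"] == pytest.approx(1.0, abs=1e-9)
        assert scores["narrow_axis"] == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_scores_zero(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.full(10, 3.0), rng.standard_normal(10), rng.standard_normal(10)])
        table = make_table(X, ["const", "a", "b"])
        assert score_pca_loading_sum(table).scores["const"] == pytest.approx(0.0, abs=1e-8)

    def test_all_components_count(self, fixtures):
        result = score_pca_loading_sum(fixtures["wide"])
        assert result.metadata["n_components"] == 29  # min(n-1, p) = 30 - 1


class TestVariance:
    def test_constant_column(self):
        table = make_table(np.ones((4, 1)), ["c"], np.array([0, 0, 1, 1]))
        assert score_variance(table).scores["c"] == 0.0

    def test_hand_computed_sample_variance(self):
        table = make_table(np.array([[0.0], [0.0], [1.0], [1.0]]), ["x"], np.array([0, 0, 1, 1]))
        assert score_variance(table).scores["x"] == pytest.approx(1 / 3, abs=1e-9)

    def test_scaling_is_quadratic(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(20)
        table = make_table(np.column_stack([x, 3.0 * x]), ["x", "x3"])
        scores = score_variance(table).scores
        assert scores["x3"] == pytest.approx(9.0 * scores["x"], rel=1e-12)


class TestSpearman:
    def test_worked_example(self, fixtures):
        scores = score_spearman(fixtures["spearman_example"]).scores
        assert scores["x_up"] == pytest.approx(4 / np.sqrt(20), abs=1e-9)

    def test_feature_equal_to_outcome(self):
        y = np.array([0, 1, 0, 1, 1])
        table = make_table(y.reshape(-1, 1).astype(float), ["x"], y)
        assert score_spearman(table).scores["x"] == pytest.approx(1.0, abs=1e-12)

    def test_reversed_feature_same_score(self, fixtures):
        up = score_spearman(fixtures["spearman_example"]).scores["x_up"]
        table = make_table(np.array([[4.0], [3.0], [2.0], [1.0]]), ["x_down"],
                           np.array([0, 0, 1, 1]))
        assert score_spearman(table).scores["x_down"] == pytest.approx(up, abs=1e-12)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(8)
        X = np.round(rng.standard_normal((30, 6)), 1)  # ties on purpose
        y = np.zeros(30, dtype=int)
        y[rng.permutation(30)[:10]] = 1
        table = make_table(X, outcome=y)
        scores = score_spearman(table).scores
        for j, name in enumerate(table.feature_names):
            expected = abs(spearmanr(X[:, j], y).statistic)
            assert scores[name] == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(15)
        y = np.zeros(15, dtype=int)
        y[rng.permutation(15)[:5]] = 1
        base = score_spearman(make_table(x.reshape(-1, 1), ["x"], y)).scores["x"]
        transformed = score_spearman(
            make_table(np.exp(2 * x).reshape(-1, 1), ["x"], y)
        ).scores["x"]
        assert transformed == pytest.approx(base, abs=1e-12)


class TestContracts:
    @pytest.mark.parametrize("scorer_id", DETERMINISTIC)
    def test_deterministic_scorers_bit_identical(self, scorer_id, small_synthetic):
        table, _ = small_synthetic
        a = get_scorer(scorer_id).score_table(table)
        b = get_scorer(scorer_id).score_table(table)
        assert a.scores == b.scores
        assert a.deterministic is True

    @pytest.mark.parametrize("scorer_id", ("variance", "spearman_abs"))
    def test_univariate_locality(self, scorer_id, small_synthetic):
        table, _ = small_synthetic
        before = get_scorer(scorer_id).score_table(table).scores
        reduced = drop_features(table, {table.feature_names[3], table.feature_names[40]})
        after = get_scorer(scorer_id).score_table(reduced).scores
        for f, s in after.items():
            assert s == before[f]  # bit-identical

    @pytest.mark.parametrize("scorer_id", ("variance", "pca_loading_sum"))
    def test_outcome_never_read(self, scorer_id, small_synthetic):
        table, _ = small_synthetic
        rng = np.random.default_rng(0)
        permuted = make_table(table.values, table.feature_names,
                              table.outcome[rng.permutation(table.n_samples)])
        a = get_scorer(scorer_id).score_table(table).scores
        b = get_scorer(scorer_id).score_table(permuted).scores
        assert a == b

    @pytest.mark.parametrize("scorer_id", SCORER_IDS)
    def test_scores_cover_all_features_nonnegative(self, scorer_id, small_synthetic):
        table, _ = small_synthetic
        result = get_scorer(scorer_id).score_table(table)
        assert set(result.scores) == set(table.feature_names)
        vals = np.array(list(result.scores.values()))
        assert np.all(np.isfinite(vals)) and np.all(vals >= 0)

    def test_unknown_scorer_rejected(self):
        with pytest.raises(KeyError, match="unknown scorer"):
            get_scorer("shap")

    def test_user_registered_scorer(self, small_synthetic):
        table, _ = small_synthetic
        register_scorer("range_width", lambda t: {
            f: float(t.column(f).max() - t.column(f).min()) for f in t.feature_names
        }, univariate=True)
        try:
            result = get_scorer("range_width").score_table(table)
            assert set(result.scores) == set(table.feature_names)
        finally:
            _REGISTRY.pop("range_width", None)
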