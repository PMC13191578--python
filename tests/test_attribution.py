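import numpy as np
import pytest

from aromatype.attribution import (
    AttributionResult,
    beeswarm_export,
    dependence_threshold,
    exact_shapley,
    global_importance,
    pca_scores_loadings,
    sample_background,
    shapley_attributions,
)
from aromatype.data_io import FeatureTable


def softmax_model(weights):
    """Linear-softmax probability function over 3 classes."""
    W = np.asarray(weights)

    def predict(X):
        s = np.asarray(X) @ W.T
        e = np.exp(s - s.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    return predict


class TestShapley:
    def test_single_feature_efficiency_is_exact(self):
        def model(X):
            p = np.clip(np.asarray(X)[:, 0], 0.0, 1.0)
            return np.column_stack([p, 1 - p, np.zeros_like(p)])

        bg = np.linspace(0.1, 0.9, 10).reshape(-1, 1)
        X = np.array([[0.3], [0.7]])
        attr = shapley_attributions(model, bg, X, n_permutations=20, seed=0)
        expected = X[:, 0] - bg.mean()
        np.testing.assert_allclose(attr.values[0, :, 0], expected, atol=1e-12)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(1)
        model = softmax_model([[0.4, -0.2], [0.0, 0.3], [-0.4, -0.1]])
        bg = rng.normal(0, 1, (30, 2))
        X = rng.normal(0, 1, (10, 2))
        attr = shapley_attributions(model, bg, X, n_permutations=200, seed=2)
        oracle = exact_shapley(model, bg, X)
        scale = np.abs(oracle).max()
        assert np.abs(attr.values - oracle).max() <= 0.02 * max(scale, 1.0)

    def test_efficiency_residuals_small(self):
        rng = np.random.default_rng(3)
        model = softmax_model(rng.normal(0, 0.5, (3, 4)))
        bg = rng.normal(0, 1, (50, 4))
        X = rng.normal(0, 1, (20, 4))
        attr = shapley_attributions(model, bg, X, n_permutations=200, seed=4)
        assert attr.efficiency_residuals().mean() < 0.02

    def test_symmetry_of_duplicated_feature(self):
        rng = np.random.default_rng(5)

        def model(X):
            X = np.asarray(X)
            s = X[:, 0] + X[:, 1]  # exactly interchangeable features
            p = 1 / (1 + np.exp(-s))
            return np.column_stack([p, 1 - p, np.zeros_like(p)])

        z = rng.normal(0, 1, 40)
        bg = np.column_stack([z, z])  # identical columns
        x = rng.normal(0, 1, 10)
        X = np.column_stack([x, x])
        attr = shapley_attributions(model, bg, X, n_permutations=300, seed=6)
        np.testing.assert_allclose(
            attr.values[0, :, 0], attr.values[0, :, 1], atol=0.02
        )

    def test_ignored_feature_gets_no_credit(self):
        rng = np.random.default_rng(7)
        model = softmax_model([[0.5, 0.0], [-0.5, 0.0], [0.0, 0.0]])
        bg = rng.normal(0, 1, (30, 2))
        X = rng.normal(0, 1, (15, 2))
        attr = shapley_attributions(model, bg, X, n_permutations=100, seed=8)
        assert np.abs(attr.values[:, :, 1]).mean() < 1e-12

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        model = softmax_model(rng.normal(size=(3, 3)))
        bg = rng.normal(0, 1, (20, 3))
        X = rng.normal(0, 1, (5, 3))
        a = shapley_attributions(model, bg, X, n_permutations=50, seed=10)
        b = shapley_attributions(model, bg, X, n_permutations=50, seed=10)
        np.testing.assert_array_equal(a.values, b.values)

    def test_background_required(self):
        with pytest.raises(ValueError, match="non-empty"):
            shapley_attributions(
                softmax_model(np.zeros((3, 2))), np.empty((0, 2)), np.ones((1, 2))
            )


class TestGlobalImportance:
    def test_zero_model_all_zero(self):
        def model(X):
            n = len(np.asarray(X))
            return np.tile([1 / 3, 1 / 3, 1 / 3], (n, 1))

        bg = np.random.default_rng(0).normal(size=(10, 2))
        attr = shapley_attributions(model, bg, bg[:4], n_permutations=20, seed=0)
        imp = global_importance(attr)
        np.testing.assert_allclose(imp["pooled"], 0.0, atol=1e-15)

    def test_pooled_is_class_mean(self):
        rng = np.random.default_rng(1)
        model = softmax_model(rng.normal(size=(3, 3)))
        bg = rng.normal(size=(15, 3))
        attr = shapley_attributions(model, bg, bg[:5], n_permutations=30, seed=1)
        imp = global_importance(attr)
        np.testing.assert_allclose(imp["pooled"], imp["per_class"].mean(axis=0))

    def test_dominant_marker_ranks_first(self):
        rng = np.random.default_rng(2)
        model = softmax_model([[2.0, 0.05, 0.05], [-2.0, 0.0, 0.0], [0.0, -0.05, -0.05]])
        bg = rng.normal(0, 1, (40, 3))
        X = rng.normal(0, 1, (20, 3))
        attr = shapley_attributions(model, bg, X, n_permutations=100, seed=3)
        assert int(np.argmax(global_importance(attr)["pooled"])) == 0


def make_attr(x, shap, feature="rutin", cls=0):
    n = len(x)
    values = np.zeros((3, n, 1))
    values[cls, :, 0] = shap
    return AttributionResult(
        [feature], [str(i) for i in range(n)], values,
        np.zeros(3), np.asarray(x).reshape(-1, 1), np.full((n, 3), 1 / 3),
    )


class TestDependenceThreshold:
    def test_recovers_planted_crossing(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(5.0, 20.0, 300)
        crossing = 12.5
        shap = 0.02 * (x - crossing) + rng.normal(0, 0.005, 300)
        attr = make_attr(x, shap)
        got = dependence_threshold(attr, "rutin", 0)
        assert got == pytest.approx(crossing, rel=0.10)

    def test_no_sign_change_returns_none(self):
        x = np.linspace(0, 10, 50)
        attr = make_attr(x, np.full(50, 0.1))
        assert dependence_threshold(attr, "rutin", 0) is None

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 60)
        shap = x - 0.4
        attr = make_attr(x, shap)
        assert dependence_threshold(attr, "rutin", 0) == dependence_threshold(
            attr, "rutin", 0
        )

    def test_requires_ten_samples(self):
        attr = make_attr(np.arange(5.0), np.arange(5.0) - 2)
        with pytest.raises(ValueError, match=">= 10"):
            dependence_threshold(attr, "rutin", 0)


class TestBeeswarmAndBackground:
    def test_beeswarm_pairs_align(self):
        rng = np.random.default_rng(0)
        model = softmax_model(rng.normal(size=(3, 2)))
        bg = rng.normal(size=(10, 2))
        X = rng.normal(size=(6, 2))
        attr = shapley_attributions(model, bg, X, n_permutations=20, seed=0)
        pairs = beeswarm_export(attr, cls=1)
        assert set(pairs) == {"x0", "x1"}
        np.testing.assert_array_equal(pairs["x0"][:, 0], X[:, 0])
        np.testing.assert_array_equal(pairs["x0"][:, 1], attr.values[1, :, 0])

    def test_background_subsampling(self, small_survey):
        bg = sample_background(small_survey, max_rows=50, seed=0)
        assert bg.n_samples == 50
        assert set(bg.sample_ids) <= set(small_survey.sample_ids)
        small = sample_background(small_survey, max_rows=10**6, seed=0)
        assert small.n_samples == small_survey.n_samples


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=30)
        X = np.outer(u, [1.0, 2.0, -1.0]) + 5.0
        _, _, evr = pca_scores_loadings(X, n_components=2)
        assert evr[0] == pytest.approx(1.0)

    def test_variance_fractions_valid(self, blob_table):
        _, _, evr = pca_scores_loadings(blob_table.values, n_components=3)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-12

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(10, 3, size=(40, 4))
        scores, loadings, _ = pca_scores_loadings(X, n_components=4)
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        np.testing.assert_allclose(scores @ loadings.T, Z, atol=1e-8)

    def test_component_bound_enforced(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_scores_loadings(np.random.default_rng(0).normal(size=(5, 2)), 3)
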