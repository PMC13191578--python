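import numpy as np
import pytest

from aromatype.data_io import FeatureTable
from aromatype.separability import (
    GAUSSIAN_FWHM,
    RESOLUTION_CONSTANT,
    SeparabilityScores,
    filter_separable,
    peak_stats,
    score_all,
    separation_index,
)

from conftest import exact_moments_sample


class TestPeakStats:
    def test_gaussian_closed_form(self):
        x = exact_moments_sample(0.0, 1.0, 200, seed=1)
        center, width = peak_stats(x, "gaussian")
        assert center == pytest.approx(0.0, abs=1e-12)
        assert width == pytest.approx(2.0 * np.sqrt(2.0 * np.log(2.0)), abs=1e-12)
        assert width == pytest.approx(2.3548, abs=1e-4)

    def test_gaussian_matches_sample_moments(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(3.0, 2.0, size=500)
        center, width = peak_stats(x, "gaussian")
        assert center == pytest.approx(np.mean(x))
        assert width == pytest.approx(GAUSSIAN_FWHM * np.std(x, ddof=1))

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError, match="zero spread"):
            peak_stats([3.0, 3.0, 3.0], "gaussian")
        with pytest.raises(ValueError, match="zero spread"):
            peak_stats([3.0, 3.0, 3.0], "kde")

    def test_kde_recovers_normal_peak(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 1.0, size=100_000)
        center, width = peak_stats(x, "kde")
        assert center == pytest.approx(5.0, rel=0.05, abs=0.05)
        assert width == pytest.approx(GAUSSIAN_FWHM, rel=0.05)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            peak_stats([1.0], "gaussian")


class TestSeparationIndex:
    def test_formula_arithmetic(self):
        a = exact_moments_sample(0.0, 1.0, 100, seed=0)
        b = exact_moments_sample(10.0, 1.0, 100, seed=1)
        f = separation_index(a, b, "gaussian")
        expected = RESOLUTION_CONSTANT * 10.0 / (2.0 * GAUSSIAN_FWHM)
        assert f == pytest.approx(expected, abs=1e-9)
        assert f == pytest.approx(2.5055, abs=1e-4)

    def test_threshold_location(self):
        # a 4-sigma mean shift sits just above the 0.8 screening threshold
        a = exact_moments_sample(0.0, 1.0, 100, seed=0)
        b = exact_moments_sample(4.0, 1.0, 100, seed=1)
        f = separation_index(a, b, "gaussian")
        assert f == pytest.approx(1.0022, abs=1e-4)
        assert f > 0.8

    def test_identical_samples_zero(self):
        x = exact_moments_sample(2.0, 0.5, 50, seed=3)
        assert separation_index(x, x, "gaussian") == 0.0

    def test_symmetry_exact(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 40), rng.normal(2, 3, 60)
        for method in ("gaussian", "kde"):
            assert separation_index(a, b, method) == separation_index(b, a, method)

    @pytest.mark.parametrize("method", ["gaussian", "kde"])
    @pytest.mark.parametrize("scale,shift", [(2.5, 0.0), (0.3, -7.0), (10.0, 100.0)])
    def test_affine_equivariance(self, method, scale, shift):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 300), rng.normal(3, 1.5, 300)
        f0 = separation_index(a, b, method)
        f1 = separation_index(scale * a + shift, scale * b + shift, method)
        assert f1 == pytest.approx(f0, rel=1e-8)

    def test_kde_agrees_with_gaussian_limit(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 1.0, 10_000)
        b = rng.normal(3.0, 1.0, 10_000)
        f_kde = separation_index(a, b, "kde")
        closed_form = RESOLUTION_CONSTANT * 3.0 / (2.0 * GAUSSIAN_FWHM)
        assert f_kde == pytest.approx(closed_form, rel=0.05)


class TestScoreAll:
    def make_table(self, columns, labels):
        values = np.column_stack(columns)
        return FeatureTable(
            [f"s{i}" for i in range(values.shape[0])],
            [f"f{j}" for j in range(values.shape[1])],
            values,
            np.asarray(labels),
        )

    def test_identical_classes_score_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 1, 30)
        labels = [0] * 10 + [1] * 10 + [2] * 10
        # same distribution in all classes: shuffle-free identical draws
        table = self.make_table([np.concatenate([x[:10]] * 3)], labels)
        scores = score_all(table)
        assert np.allclose(scores.values, 0.0)

    def test_planted_shift_in_one_class(self):
        rng = np.random.default_rng(1)
        col = np.concatenate(
            [rng.normal(5 + 5.0, 1.0, 50), rng.normal(5, 1, 50), rng.normal(5, 1, 50)]
        )
        labels = [0] * 50 + [1] * 50 + [2] * 50
        scores = score_all(self.make_table([col], labels))
        f = scores.of("f0")
        assert f["f01"] > 0.8 and f["f02"] > 0.8
        assert f["f12"] < 0.3

    def test_matches_per_feature_calls(self):
        rng = np.random.default_rng(2)
        cols = [rng.normal(c, 1, 60) for c in (0, 3, 10)]
        labels = np.array([0] * 20 + [1] * 20 + [2] * 20)
        table = self.make_table(cols, labels)
        scores = score_all(table)
        for j, name in enumerate(table.feature_names):
            for k, (a, b) in enumerate([(0, 1), (1, 2), (0, 2)]):
                direct = separation_index(
                    table.values[labels == a, j], table.values[labels == b, j]
                )
                assert scores.values[j, k] == pytest.approx(direct)

    def test_zero_spread_feature_warns_and_scores_zero(self):
        rng = np.random.default_rng(3)
        const = np.ones(30)
        noise = rng.normal(0, 1, 30)
        labels = [0] * 10 + [1] * 10 + [2] * 10
        table = self.make_table([const, noise], labels)
        with pytest.warns(RuntimeWarning, match="zero spread"):
            scores = score_all(table)
        assert np.allclose(scores.values[0], 0.0)

    def test_missing_class_rejected(self):
        table = self.make_table([np.arange(10.0)], [0] * 5 + [1] * 5)
        with pytest.raises(ValueError, match="class 2"):
            score_all(table)


class TestFilter:
    def scores(self, rows):
        return SeparabilityScores([f"f{i}" for i in range(len(rows))], np.array(rows))

    def test_any_rule_keeps_single_strong_pair(self):
        assert filter_separable(self.scores([[0.9, 0.1, 0.1]]), rule="any") == ["f0"]

    def test_all_rule_drops_single_strong_pair(self):
        assert filter_separable(self.scores([[0.9, 0.1, 0.1]]), rule="all") == []

    def test_strict_threshold_boundary(self):
        assert filter_separable(self.scores([[0.8, 0.8, 0.8]])) == []
        assert filter_separable(self.scores([[0.8 + 1e-12, 0.0, 0.0]])) == ["f0"]

    def test_order_preserved(self):
        got = filter_separable(self.scores([[0.9, 0, 0], [0.1, 0, 0], [0, 0.95, 0]]))
        assert got == ["f0", "f2"]
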