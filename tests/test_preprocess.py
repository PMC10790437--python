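import numpy as np
import pytest

from sncsig import preprocess, simcohort
from sncsig.preprocess import (
    filter_low_expression,
    impute_missing,
    mask_outliers,
    normalize_and_standardize,
    preprocess_pipeline,
    size_factors_median_of_ratios,
    standardize_features,
)

from conftest import toy_count_matrix


class TestFilterLowExpression:
    def test_boundary_at_min_total(self):
        cm = toy_count_matrix(np.array([[999] + [0] * 9, [1000] + [0] * 9]))
        out = filter_low_expression(cm, 1000)
        assert list(out.feature_ids) == ["f1"]

    def test_three_feature_toy(self):
        rows = [
            np.full(10, 50),    # sum 500
            np.full(10, 100),   # sum 1000
            np.full(10, 1200),  # sum 12000
        ]
        out = filter_low_expression(toy_count_matrix(np.array(rows)), 1000)
        assert out.n_features == 2
        assert list(out.feature_ids) == ["f1", "f2"]

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            filter_low_expression(toy_count_matrix(np.zeros((3, 4), dtype=int)))


class TestSizeFactors:
    def test_identical_samples_equal_factors(self):
        col = np.array([10, 200, 3000])
        cm = toy_count_matrix(np.column_stack([col, col]))
        f = size_factors_median_of_ratios(cm)
        assert f[0] == pytest.approx(f[1])

    def test_doubling_scale_equivariance(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 500, size=20)
        cm = toy_count_matrix(np.column_stack([a, 2 * a]))
        f = size_factors_median_of_ratios(cm)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_hand_computed_two_by_two(self):
        cm = toy_count_matrix(np.array([[100, 200], [10, 20]]))
        f = size_factors_median_of_ratios(cm)
        # geometric means {sqrt(100*200), sqrt(10*20)}; medians of per-sample
        # ratios are {1/sqrt(2), sqrt(2)}
        assert f[0] == pytest.approx(100 / np.sqrt(100 * 200))
        assert f[1] == pytest.approx(200 / np.sqrt(100 * 200))

    def test_poscounts_fallback_warns(self):
        cm = toy_count_matrix(np.array([[0, 10], [5, 0]]))
        with pytest.warns(RuntimeWarning):
            f = size_factors_median_of_ratios(cm)
        assert np.all(f > 0)


class TestNormalizeStandardize:
    def test_feature_mean_zero_sd_one(self, clean_cohort):
        _, counts, _, _ = clean_cohort
        filt = filter_low_expression(counts)
        em = normalize_and_standardize(filt)
        assert np.abs(em.values.mean(axis=1)).max() < 1e-8
        assert np.abs(em.values.std(axis=1) - 1).max() < 1e-8

    def test_constant_feature_warns(self):
        cm = toy_count_matrix(np.full((1, 4), 7))
        with pytest.warns(RuntimeWarning):
            normalize_and_standardize(cm, np.ones(4))

    def test_order_preserved_monotone(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(1, 1000, size=(4, 8))
            cm = toy_count_matrix(counts)
            factors = size_factors_median_of_ratios(cm)
            em = normalize_and_standardize(cm, factors)
            norm = counts / factors[None, :]
            for i in range(4):
                assert np.array_equal(
                    np.argsort(norm[i], kind="stable"),
                    np.argsort(em.values[i], kind="stable"),
                )


class TestMaskOutliers:
    def _em(self, values):
        values = np.asarray(values, dtype=float)
        return preprocess.ExpressionMatrix(
            values=values,
            mask=np.zeros(values.shape, dtype=bool),
            size_factors=np.ones(values.shape[1]),
            feature_ids=np.array([f"f{i}" for i in range(values.shape[0])], dtype=object),
            sample_ids=np.array([f"s{j}" for j in range(values.shape[1])], dtype=object),
        )

    def test_hand_computed_five_vector(self):
        v = np.array([[0.0, 0.0, 0.0, 0.0, 10.0]])
        z10 = (10 - v.mean()) / v.std(ddof=1)  # = 8/sqrt(20) ~ 1.789
        out = mask_outliers(self._em(v), 3.0)
        assert not out.mask.any()  # |z| = 1.79 < 3
        out = mask_outliers(self._em(v), z_threshold=1.5)
        assert out.mask[0, 4] and out.mask.sum() == 1
        assert z10 == pytest.approx(8 / np.sqrt(20))

    def test_constant_feature_no_masking(self):
        out = mask_outliers(self._em(np.full((1, 6), 3.0)))
        assert not out.mask.any()

    def test_infinite_threshold_identity(self):
        rng = np.random.default_rng(0)
        em = self._em(rng.normal(size=(3, 30)))
        out = mask_outliers(em, np.inf)
        np.testing.assert_array_equal(out.mask, em.mask)

    def test_idempotence_with_frozen_reference(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(5, 100))
        v[0, 0] = 25.0
        once = mask_outliers(self._em(v), 3.0)
        twice = mask_outliers(once, 3.0)
        np.testing.assert_array_equal(once.mask, twice.mask)


class TestImpute:
    def _masked_em(self, values, mask):
        values = np.asarray(values, dtype=float).copy()
        mask = np.asarray(mask, dtype=bool)
        values[mask] = np.nan
        return preprocess.ExpressionMatrix(
            values=values,
            mask=mask,
            size_factors=np.ones(values.shape[1]),
            feature_ids=np.array([f"f{i}" for i in range(values.shape[0])], dtype=object),
            sample_ids=np.array([f"s{j}" for j in range(values.shape[1])], dtype=object),
        )

    def test_no_masked_cells_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(3, 10))
        em = self._masked_em(v, np.zeros_like(v, dtype=bool))
        out = impute_missing(em)
        np.testing.assert_array_equal(out.values, v)

    def test_feature_median_single_cell(self):
        v = np.array([[1.0, 2.0, 3.0, 4.0, 100.0]])
        mask = np.array([[False, False, False, False, True]])
        out = impute_missing(self._masked_em(v, mask), method="feature_median")
        assert out.values[0, 4] == pytest.approx(np.median([1, 2, 3, 4]))

    def test_entirely_missing_feature_errors(self):
        v = np.ones((2, 4))
        mask = np.zeros_like(v, dtype=bool)
        mask[1] = True
        with pytest.raises(ValueError, match="f1"):
            impute_missing(self._masked_em(v, mask))

    def test_unmasked_cells_untouched(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(10, 30))
        mask = rng.random(v.shape) < 0.1
        mask[:, 0] = False
        em = self._masked_em(v, mask)
        for method in ("feature_median", "knn", "iterative_forest"):
            out = impute_missing(em, method=method, seed=0, n_estimators=5)
            np.testing.assert_array_equal(out.values[~mask], v[~mask])

    def test_forest_beats_median_on_structured_data(self):
        # correlated features: regression imputation should beat the
        # per-feature median on RMSE against the true values
        wins = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            latent = rng.normal(size=60)
            v = latent[None, :] * rng.uniform(0.5, 2.0, size=(15, 1))
            v = v + rng.normal(scale=0.3, size=v.shape)
            mask = rng.random(v.shape) < 0.05
            em = self._masked_em(v, mask)
            rf = impute_missing(em, method="iterative_forest", seed=0, n_estimators=10)
            med = impute_missing(em, method="feature_median")
            rmse_rf = np.sqrt(np.mean((rf.values[mask] - v[mask]) ** 2))
            rmse_med = np.sqrt(np.mean((med.values[mask] - v[mask]) ** 2))
            wins += rmse_rf <= rmse_med
        assert wins >= 2

    def test_unknown_method(self):
        em = self._masked_em(np.ones((1, 3)), np.array([[True, False, False]]))
        with pytest.raises(ValueError):
            impute_missing(em, method="magic")


class TestPipeline:
    def test_deterministic_rerun(self, clean_cohort):
        _, counts, _, _ = clean_cohort
        em1, _ = preprocess_pipeline(counts, impute_method="iterative_forest", seed=7)
        em2, _ = preprocess_pipeline(counts, impute_method="iterative_forest", seed=7)
        np.testing.assert_array_equal(em1.values, em2.values)
        np.testing.assert_array_equal(em1.mask, em2.mask)

    def test_scale_invariance_one_sample(self):
        # scaling one zero-free sample by k multiplies its size factor by k
        # relative to every other sample (the common geometric-mean shift
        # cancels), and leaves standardized values unchanged
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 2000, size=(30, 12))  # zero-free
        cm = toy_count_matrix(counts)
        scaled = counts.copy()
        scaled[:, 4] *= 7
        cm2 = toy_count_matrix(scaled)
        f1 = size_factors_median_of_ratios(cm)
        f2 = size_factors_median_of_ratios(cm2)
        keep = [j for j in range(12) if j != 4]
        np.testing.assert_allclose(
            (f2[4] / f2[keep]) / (f1[4] / f1[keep]), 7.0, rtol=1e-10
        )
        # pseudocount 0 so the per-sample scale cancels exactly in the logs
        em1 = normalize_and_standardize(cm, f1, pseudocount=0.0)
        em2 = normalize_and_standardize(cm2, f2, pseudocount=0.0)
        np.testing.assert_allclose(em1.values, em2.values, atol=1e-6)

    def test_standardized_after_imputation(self, default_cohort):
        _, counts, _, _ = default_cohort
        em, _ = preprocess_pipeline(counts, impute_method="feature_median")
        assert np.abs(em.values.mean(axis=1)).max() < 1e-8
        sd = em.values.std(axis=1)
        assert np.abs(sd[sd > 0] - 1).max() < 1e-8

    def test_sample_depth_qc_flag(self, clean_cohort):
        _, counts, _, _ = clean_cohort
        depth = counts.counts.sum(axis=0)
        cutoff = int(np.sort(depth)[2]) + 1
        em, _ = preprocess_pipeline(
            counts, impute_method="feature_median", min_sample_reads=cutoff
        )
        assert em.values.shape[1] == (depth >= cutoff).sum()
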