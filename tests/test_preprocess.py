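"""Tests for background correction, quantile normalization, probe handling
and kNN imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mirsig.preprocess import (
    NormexpParams,
    average_probes,
    collapse_multiprobe_genes,
    fit_normexp,
    knn_impute,
    normexp_correct,
    normexp_signal,
    quantile_normalize,
)


class TestNormexp:
    def test_vanishing_background_returns_input(self):
        p = NormexpParams(mu=0.0, sigma=1e-8, alpha_exp=37.0)
        assert normexp_signal(np.array([100.0]), p)[0] == pytest.approx(100.0, abs=1e-6)

    def test_output_positive_deep_in_background(self):
        p = NormexpParams(mu=50.0, sigma=4.0, alpha_exp=30.0)
        x = p.mu - 5 * p.sigma
        assert normexp_signal(np.array([x]), p)[0] > 0

    def test_posterior_mean_matches_quadrature(self):
        """E[S | X=x] by direct numerical integration of the convolution."""
        p = NormexpParams(mu=10.0, sigma=2.0, alpha_exp=50.0)
        x = 12.0

        def integrand_num(s):
            return s * stats.expon.pdf(s, scale=p.alpha_exp) * stats.norm.pdf(x - s, p.mu, p.sigma)

        def integrand_den(s):
            return stats.expon.pdf(s, scale=p.alpha_exp) * stats.norm.pdf(x - s, p.mu, p.sigma)

        num, _ = integrate.quad(integrand_num, 0, np.inf, limit=200)
        den, _ = integrate.quad(integrand_den, 0, np.inf, limit=200)
        assert normexp_signal(np.array([x]), p)[0] == pytest.approx(num / den, abs=1e-6)

    def test_monotone_in_x(self):
        p = NormexpParams(mu=100.0, sigma=10.0, alpha_exp=80.0)
        xs = np.linspace(0, 500, 400)
        out = normexp_signal(xs, p)
        assert (np.diff(out) > 0).all()

    def test_parameter_recovery_from_simulated_convolution(self, rng):
        mu, sigma, alpha = 100.0, 15.0, 60.0
        x = rng.normal(mu, sigma, 5000) + rng.exponential(alpha, 5000)
        fit = fit_normexp(x)
        assert fit.mu == pytest.approx(mu, rel=0.10)
        assert fit.sigma == pytest.approx(sigma, rel=0.10)
        assert fit.alpha_exp == pytest.approx(alpha, rel=0.10)

    def test_correct_estimates_per_sample(self, make_dataset, rng):
        x = rng.normal(100, 15, size=(300, 4)) + rng.exponential(60, size=(300, 4))
        ds = make_dataset(x, 2, 2)
        out = normexp_correct(ds, "estimate")
        assert (out.matrix() > 0).all()
        assert out.values.shape == ds.values.shape

    def test_too_few_values_for_estimation(self, make_dataset, rng):
        ds = make_dataset(rng.normal(100, 10, size=(10, 4)), 2, 2)
        with pytest.raises(ValueError, match="at least 50"):
            normexp_correct(ds, "estimate")


class TestQuantileNormalize:
    def test_toy_two_columns(self, make_dataset):
        ds = make_dataset(np.array([[2.0, 1.0], [4.0, 3.0], [6.0, 5.0]]), 1, 1)
        out = quantile_normalize(ds)
        expected = np.array([[1.5, 1.5], [3.5, 3.5], [5.5, 5.5]])
        np.testing.assert_allclose(out.matrix(), expected)

    def test_identical_columns_are_a_fixed_point(self, make_dataset, rng):
        col = rng.normal(size=30)
        ds = make_dataset(np.column_stack([col] * 4), 2, 2)
        out = quantile_normalize(ds)
        np.testing.assert_allclose(out.matrix(), ds.matrix(), atol=1e-12)

    def test_postcondition_and_idempotence_on_complete_data(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(50, 6)), 3, 3)
        out = quantile_normalize(ds)
        X = out.matrix()
        ref = np.sort(X, axis=0).mean(axis=1)
        for j in range(X.shape[1]):
            np.testing.assert_allclose(np.sort(X[:, j]), ref, atol=1e-12)
        twice = quantile_normalize(out)
        np.testing.assert_allclose(twice.matrix(), X, atol=1e-12)

    def test_rank_order_preserved_and_missing_stay_missing(self, make_dataset, rng):
        mat = rng.normal(size=(30, 5))
        mat[3, 0] = np.nan
        mat[10, 2] = np.nan
        ds = make_dataset(mat, 3, 2)
        out = quantile_normalize(ds).matrix()
        assert np.isnan(out[3, 0]) and np.isnan(out[10, 2])
        for j in range(5):
            obs = np.isfinite(mat[:, j])
            orig_rank = np.argsort(np.argsort(mat[obs, j]))
            new_rank = np.argsort(np.argsort(out[obs, j]))
            np.testing.assert_array_equal(orig_rank, new_rank)

    def test_column_with_too_few_observed_rejected(self, make_dataset):
        mat = np.array([[1.0, np.nan], [2.0, 5.0], [3.0, np.nan]])
        with pytest.raises(ValueError, match="fewer than 2"):
            quantile_normalize(make_dataset(mat, 1, 1))


class TestAverageProbes:
    def test_mean_of_two_probes(self, make_dataset):
        ds = make_dataset(np.array([[3.0, 3.0], [5.0, 5.0]]), 1, 1)
        out = average_probes(ds, {"f000": "mirA", "f001": "mirA"})
        np.testing.assert_allclose(out.values.loc["mirA"].to_numpy(), [4.0, 4.0])

    def test_missing_values_excluded_from_mean(self, make_dataset):
        ds = make_dataset(np.array([[3.0, 1.0], [np.nan, 3.0]]), 1, 1)
        out = average_probes(ds, {"f000": "mirA", "f001": "mirA"})
        np.testing.assert_allclose(out.values.loc["mirA"].to_numpy(), [3.0, 2.0])

    def test_single_probe_renamed_only(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(3, 4)), 2, 2)
        out = average_probes(ds, {"f000": "a", "f001": "b", "f002": "c"})
        np.testing.assert_allclose(np.sort(out.matrix(), axis=0), np.sort(ds.matrix(), axis=0))

    def test_empty_probe_map_rejected(self, make_dataset, rng):
        with pytest.raises(ValueError, match="empty"):
            average_probes(make_dataset(rng.normal(size=(3, 4)), 2, 2), {})


class TestCollapseMultiprobe:
    def test_multi_probe_gene_removed(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(3, 4)), 2, 2)
        out = collapse_multiprobe_genes(ds, {"f000": "geneA", "f001": "geneB", "f002": "geneB"})
        assert out.feature_ids == ["geneA"]

    def test_all_single_probe_is_identity_up_to_renaming(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(3, 4)), 2, 2)
        out = collapse_multiprobe_genes(ds, {"f000": "a", "f001": "b", "f002": "c"})
        assert out.n_features == 3

    def test_all_multi_probe_gives_empty_dataset(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(4, 4)), 2, 2)
        out = collapse_multiprobe_genes(ds, {f"f{i:03d}": "g" for i in range(4)})
        assert out.n_features == 0


class TestKnnImpute:
    def test_no_missing_is_identity(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(10, 6)), 3, 3)
        out = knn_impute(ds, k=3)
        assert out.values.equals(ds.values)

    def test_nearest_neighbour_example(self, make_dataset):
        mat = np.array([[1.0, 2, 3], [1.0, 2, np.nan], [10.0, 20, 30]])
        ds = make_dataset(mat, 2, 1)
        out = knn_impute(ds, k=1)
        assert out.values.iloc[1, 2] == pytest.approx(3.0)

    def test_observed_cells_bit_identical(self, make_dataset, rng):
        mat = rng.normal(size=(20, 8))
        mask = rng.random(mat.shape) < 0.1
        mat_missing = np.where(mask, np.nan, mat)
        ds = make_dataset(mat_missing, 4, 4)
        out = knn_impute(ds, k=5).matrix()
        obs = ~mask
        np.testing.assert_array_equal(out[obs], mat_missing[obs])
        assert np.isfinite(out).all()

    def test_k_larger_than_candidates_uses_all(self, make_dataset):
        mat = np.array([[1.0, 2, np.nan], [1.0, 2, 4], [2.0, 3, 6]])
        ds = make_dataset(mat, 2, 1)
        out = knn_impute(ds, k=50)
        assert out.values.iloc[0, 2] == pytest.approx(5.0)  # mean of the two candidates

    def test_fully_missing_feature_is_an_error(self, make_dataset):
        mat = np.array([[np.nan, np.nan, np.nan], [1.0, 2, 3]])
        with pytest.raises(ValueError, match="no observed"):
            knn_impute(make_dataset(mat, 2, 1), k=1)

    def test_matches_sklearn_on_complete_neighbour_fixture(self, make_dataset, rng):
        """On data where every candidate row is fully observed the contract
        coincides with scikit-learn's KNNImputer (uniform weights)."""
        from sklearn.impute import KNNImputer

        mat = rng.normal(size=(15, 6))
        holes = [(2, 1), (7, 4), (11, 0)]
        for i, j in holes:
            mat[i, j] = np.nan
        ds = make_dataset(mat, 3, 3)
        ours = knn_impute(ds, k=3).matrix()
        theirs = KNNImputer(n_neighbors=3, weights="uniform").fit_transform(mat)
        for i, j in holes:
            assert ours[i, j] == pytest.approx(theirs[i, j], abs=1e-9)


class TestPipelineChain:
    def test_default_chain_runs_in_documented_order(self, make_dataset, rng):
        """normexp -> quantile -> probe averaging -> imputation, end to end on
        raw-intensity-like data with missing cells."""
        from mirsig.preprocess import PreprocessConfig, preprocess_pipeline

        x = rng.normal(100, 15, size=(200, 6)) + rng.exponential(60, size=(200, 6))
        x[rng.random(x.shape) < 0.02] = np.nan
        ds = make_dataset(x, 3, 3)
        probe_map = {f"f{i:03d}": f"mir{i // 2}" for i in range(200)}
        out = preprocess_pipeline(ds, PreprocessConfig(knn_k=3, probe_map=probe_map),
                                  background="estimate")
        assert out.n_features == 100  # two probes averaged per miRNA
        assert np.isfinite(out.matrix()).all()
        assert (out.matrix() > 0).all()
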