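"""Unit and property tests for the five outlier statistics and the
selection/consensus machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from mirsig.outliers import (
    BenchmarkConfig,
    METHODS,
    consensus_putative,
    method_accuracy,
    most_null_moments,
    score_all_methods,
    score_dataset,
    stat_copa,
    stat_most,
    stat_ort,
    stat_os,
    stat_t,
)


def _groups(n_normal, n_tumor):
    return ["normal"] * n_normal + ["tumor"] * n_tumor


class TestTStatistic:
    def test_hand_computed_example(self):
        # means 1 vs 4, pooled variance 1 -> t = 3 / sqrt(2/3)
        t = stat_t([0, 1, 2, 3, 4, 5], _groups(3, 3))
        assert t == pytest.approx(3 / math.sqrt(2 / 3), abs=1e-12)

    def test_identical_groups_give_zero(self):
        assert stat_t([1, 2, 3, 1, 2, 3], _groups(3, 3)) == pytest.approx(0.0)

    def test_constant_values_flagged_undefined(self):
        assert math.isnan(stat_t([5, 5, 5, 5, 5, 5], _groups(3, 3)))


class TestCopa:
    def test_tumor_at_median_gives_zero(self):
        vals = [1, 2, 3, 4, 5, 3, 3, 3]
        assert stat_copa(vals, _groups(5, 3)) == pytest.approx(0.0)

    def test_percentile_100_is_max_standardized_tumor(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=12)
        g = _groups(6, 6)
        got = stat_copa(vals, g, r=100)
        med = np.median(vals)
        mad = 1.4826 * np.median(np.abs(vals - med))
        assert got == pytest.approx(max((vals[6:] - med) / mad), abs=1e-12)

    def test_zero_mad_flagged(self):
        assert math.isnan(stat_copa([2.0] * 10, _groups(5, 5)))


class TestOutlierSum:
    def test_no_tumor_above_cutoff_gives_zero(self):
        vals = [0, 1, 2, 3, 4, 1.5, 2.0, 2.5]
        assert stat_os(vals, _groups(5, 3)) == pytest.approx(0.0)

    def test_single_extreme_tumor_equals_its_standardized_value(self):
        vals = [0.0, 0.5, 1.0, 1.5, 2.0, 0.7, 1.2, 30.0]
        got = stat_os(vals, _groups(5, 3))
        med = np.median(vals)
        mad = 1.4826 * np.median(np.abs(np.array(vals) - med))
        assert got == pytest.approx((30.0 - med) / mad, abs=1e-12)


class TestOrt:
    def test_no_tumor_above_cutoff_gives_zero(self):
        assert stat_ort([1, 2, 3, 4, 5, 2, 3, 3.5], _groups(5, 3)) == pytest.approx(0.0)

    def test_single_outlier_matches_hand_formula(self):
        normal = [1, 2, 3, 4, 5]
        tumor = [2.5, 3.0, 20.0]
        got = stat_ort(normal + tumor, _groups(5, 3))
        assert got == pytest.approx(oracles.ort(normal, tumor), abs=1e-12)


class TestMostNullMoments:
    def test_mu1_matches_closed_form_for_two_normals(self):
        # E[max(Z1, Z2)] = 1/sqrt(pi)
        table = most_null_moments(2, B=200_000, seed=7)
        assert table.mu[0] == pytest.approx(1 / math.sqrt(math.pi), abs=0.01)

    def test_mu_full_sum_is_near_zero(self):
        table = most_null_moments(8, B=50_000, seed=7)
        assert abs(table.mu[-1]) < 0.05
        assert (table.sigma > 0).all()

    def test_same_seed_gives_identical_table(self):
        a = most_null_moments(5, B=2000, seed=3)
        b = most_null_moments(5, B=2000, seed=3)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)


class TestMost:
    def test_tumor_at_normal_median_forced_by_formula(self):
        table = most_null_moments(4, B=5000, seed=1)
        normal = [1.0, 2.0, 3.0, 4.0, 5.0]
        tumor = [3.0, 3.0, 3.0, 3.0]
        got = stat_most(normal + tumor, _groups(5, 4), table)
        assert got == pytest.approx(max(-table.mu / table.sigma), abs=1e-12)

    def test_single_shifted_sample_maximizes_at_small_k(self):
        table = most_null_moments(6, B=20_000, seed=1)
        rng = np.random.default_rng(4)
        normal = rng.normal(size=8)
        tumor = np.append(rng.normal(size=5), 12.0)
        med = np.median(normal)
        mad = 1.4826 * np.median(np.abs(normal - med))
        z = np.sort((tumor - med) / mad)[::-1]
        M = np.cumsum(z)
        ks = (M - table.mu) / table.sigma
        assert int(np.argmax(ks)) == 0  # k = 1 dominates


@pytest.mark.parametrize("method,oracle,kw", [
    ("t", oracles.t_pooled, {}),
    ("COPA", oracles.copa, {"r": 90.0}),
    ("OS", oracles.outlier_sum, {}),
    ("ORT", oracles.ort, {}),
])
def test_statistics_match_loop_oracles_on_random_data(method, oracle, kw, rng):
    fn = {"t": stat_t, "COPA": stat_copa, "OS": stat_os, "ORT": stat_ort}[method]
    for _ in range(50):
        normal = rng.normal(size=10)
        tumor = rng.normal(size=10)
        got = fn(list(normal) + list(tumor), _groups(10, 10), **kw)
        want = oracle(list(normal), list(tumor), **kw)
        assert got == pytest.approx(want, abs=1e-10)


def test_most_matches_loop_oracle_on_random_data(rng):
    table = most_null_moments(10, B=20_000, seed=5)
    for _ in range(50):
        normal = rng.normal(size=10)
        tumor = rng.normal(size=10)
        got = stat_most(list(normal) + list(tumor), _groups(10, 10), table)
        want = oracles.most(list(normal), list(tumor), table.mu, table.sigma)
        assert got == pytest.approx(want, abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    shift=st.floats(-50, 50),
    scale=st.floats(0.1, 20),
    seed=st.integers(0, 10_000),
)
def test_robust_statistics_are_location_scale_invariant(shift, scale, seed):
    """COPA/OS/ORT/MOST are built on medians and MADs, so x -> a*x + b with
    a > 0 must leave them unchanged."""
    rng = np.random.default_rng(seed)
    normal = list(rng.normal(size=8))
    tumor = list(rng.normal(size=8))
    g = _groups(8, 8)
    table = most_null_moments(8, B=5000, seed=1)
    for fn, kw in [
        (stat_copa, {}),
        (stat_os, {}),
        (stat_ort, {}),
        (stat_most, {"null_table": table}),
    ]:
        base = fn(normal + tumor, g, **kw)
        moved = fn([scale * x + shift for x in normal + tumor], g, **kw)
        assert moved == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestScoreDataset:
    def test_top_fraction_count_is_ceiling(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(40, 12)), 6, 6)
        tab = score_dataset(ds, "t", selection_fraction=0.05)
        assert int(tab.table["selected"].sum()) == 2  # ceil(0.05 * 40)

    def test_down_shifted_feature_gets_down_direction_and_is_selectable(self, make_dataset, rng):
        mat = rng.normal(8, 1, size=(40, 12))
        mat[0, 9:] -= 6.0  # three tumour samples strongly down
        ds = make_dataset(mat, 6, 6)
        tab = score_dataset(ds, "MOST", selection_fraction=0.05)
        row = tab.table.loc["f000"]
        assert row["direction"] == "down"
        assert bool(row["selected"])

    def test_ranks_are_a_permutation_and_ties_break_by_id(self, make_dataset):
        # all features identical -> identical statistics -> lexicographic ranks
        mat = np.tile(np.array([0, 1, 2, 5, 6, 7.0]), (5, 1))
        ds = make_dataset(mat, 3, 3)
        tab = score_dataset(ds, "t", selection_fraction=0.2)
        assert sorted(tab.table["rank"]) == [1, 2, 3, 4, 5]
        assert list(tab.table.sort_values("rank").index) == sorted(ds.feature_ids)

    def test_undefined_statistics_rank_last_and_are_never_selected(self, make_dataset, rng):
        mat = rng.normal(size=(10, 10))
        mat[3] = 7.0  # constant feature: zero variance and zero MAD
        ds = make_dataset(mat, 5, 5)
        tab = score_dataset(ds, "t", selection_fraction=0.5)
        assert tab.table.loc["f003", "rank"] == 10
        assert not tab.table.loc["f003", "selected"]


class TestConsensus:
    def _tables(self, make_dataset, rng, n=20):
        ds = make_dataset(rng.normal(size=(n, 12)), 6, 6)
        return score_all_methods(ds, BenchmarkConfig(selection_fraction=0.2))

    def test_min_methods_boundary_is_union(self, make_dataset, rng):
        tables = self._tables(make_dataset, rng)
        union = set().union(*(t.selected for t in tables.values()))
        assert consensus_putative(tables.values(), min_methods=1) == union

    def test_feature_needs_at_least_min_methods(self, make_dataset, rng):
        tables = self._tables(make_dataset, rng)
        putative = consensus_putative(tables.values(), min_methods=3)
        for f in putative:
            count = sum(f in t.selected for t in tables.values())
            assert count >= 3

    def test_differing_universes_rejected(self, make_dataset, rng):
        t1 = score_dataset(make_dataset(rng.normal(size=(10, 12)), 6, 6), "t")
        t2 = score_dataset(
            make_dataset(rng.normal(size=(11, 12)), 6, 6), "COPA"
        )
        with pytest.raises(ValueError, match="universe"):
            consensus_putative([t1, t2])


class TestMethodAccuracy:
    def test_median_of_proportions(self, make_dataset, rng):
        datasets = [make_dataset(rng.normal(size=(40, 12)), 6, 6, dataset_id=f"d{i}") for i in range(3)]
        acc, per_ds = method_accuracy(datasets, BenchmarkConfig(selection_fraction=0.2))
        assert set(acc.index) == set(METHODS)
        for m in METHODS:
            assert acc[m] == pytest.approx(np.nanmedian(per_ds.loc[m].to_numpy()))
        assert ((per_ds.fillna(0) >= 0) & (per_ds.fillna(0) <= 1)).all().all()

    def test_single_dataset_accuracy_is_its_proportion(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(40, 12)), 6, 6)
        acc, per_ds = method_accuracy([ds])
        assert acc.equals(per_ds.iloc[:, 0].rename("accuracy"))
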