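"""Monte-Carlo engines against exhaustive enumeration, closed forms and
each other's limiting behaviour."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from cooccur import (
    BindingProfile,
    GenomicInterval,
    SimpleModelSpec,
    build_matrix,
    ci_distribution,
    ci_index,
    fl_test,
    hybrid_limit_pmf,
    hybrid_test,
    independent_test,
    make_simple_model,
    merge_results,
    partition_pool,
    permutation_test,
    run_partitioned,
    survey_then_full,
)

from conftest import (
    assert_pmfs_close,
    empirical_pmf,
    enumerate_hybrid_null,
    enumerate_independent_null,
    enumerate_permutation_null,
    exceedance,
    mc_se,
)


def _simple_matrix(m, singles=0):
    prof = make_simple_model(SimpleModelSpec(m=m, singletons_A=singles, singletons_B=singles))
    return build_matrix(list(prof))


class TestPermutationTest:
    def test_null_distribution_matches_enumeration(self):
        matrix = _simple_matrix(2, singles=1)
        exact = enumerate_permutation_null(matrix, range(matrix.n), 3)
        res = permutation_test(matrix, "A", "B", iterations=20_000, seed=11, keep_null=True)
        assert set(empirical_pmf(res.null_sample)) <= set(exact)
        assert_pmfs_close(empirical_pmf(res.null_sample), exact, res.iterations)
        expected_p = exceedance(exact, res.observed)
        assert abs(res.p_hat - expected_p) <= 3 * mc_se(expected_p, res.iterations)

    def test_zero_observed_gives_p_one(self):
        a = BindingProfile("A", [GenomicInterval("chr1", 0, 10)])
        b = BindingProfile("B", [GenomicInterval("chr1", 100, 110)])
        res = permutation_test(build_matrix([a, b]), "A", "B", iterations=500, seed=0)
        assert res.observed == 0.0
        assert res.p_hat == 1.0

    def test_empty_pool_rejected(self):
        a = BindingProfile("A", [])
        b = BindingProfile("B", [])
        with pytest.raises(ValueError):
            permutation_test(build_matrix([a, b]), "A", "B", iterations=10, seed=0)


class TestIndependentTest:
    def test_null_distribution_matches_enumeration(self):
        matrix = _simple_matrix(2)
        exact = enumerate_independent_null(matrix, range(4), 2, 2)
        res = independent_test(matrix, "A", "B", iterations=20_000, seed=13, keep_null=True)
        assert_pmfs_close(empirical_pmf(res.null_sample), exact, res.iterations)
        expected_p = exceedance(exact, res.observed)
        assert abs(res.p_hat - expected_p) <= 3 * mc_se(expected_p, res.iterations)

    def test_dual_assignment_occurs(self):
        # with 10 pairs and independent draws, scores above the permutation
        # maximum (10) must appear: dually-assigned pairs score 4
        matrix = _simple_matrix(10)
        res = independent_test(matrix, "A", "B", iterations=5000, seed=1, keep_null=True)
        assert res.null_sample.max() > 10


class TestHybridTest:
    def test_all_singleton_null_matches_hypergeometric_limit(self):
        # m = 0 with 6 + 6 singletons: pool O empty, scheme is two
        # independent draws; null pmf must equal the closed form
        matrix = _simple_matrix(0, singles=6)
        res = hybrid_test(matrix, "A", "B", iterations=30_000, seed=17, keep_null=True)
        exact = {k: hybrid_limit_pmf(6, 6, k) for k in range(7)}
        assert_pmfs_close(empirical_pmf(res.null_sample), exact, res.iterations)

    def test_no_singleton_null_matches_permutation(self):
        # S empty: hybrid must degenerate to the permutation scheme
        matrix = _simple_matrix(4)
        hyb = hybrid_test(matrix, "A", "B", iterations=10_000, seed=19, keep_null=True)
        perm = permutation_test(matrix, "A", "B", iterations=10_000, seed=23, keep_null=True)
        ks = ks_2samp(hyb.null_sample, perm.null_sample)
        assert ks.pvalue > 0.001

    def test_mixed_pool_null_matches_enumeration(self):
        matrix = _simple_matrix(2, singles=1)
        part = partition_pool(matrix, "A", "B")
        exact = enumerate_hybrid_null(matrix, range(matrix.n), part.overlapped, 3, 3)
        res = hybrid_test(matrix, "A", "B", iterations=30_000, seed=29, keep_null=True)
        assert_pmfs_close(empirical_pmf(res.null_sample), exact, res.iterations)
        expected_p = exceedance(exact, res.observed)
        assert abs(res.p_hat - expected_p) <= 3 * mc_se(expected_p, res.iterations)


class TestFLTest:
    def test_two_factor_dataset_equals_permutation(self):
        matrix = _simple_matrix(3, singles=2)
        fl = fl_test(matrix, "A", "B", iterations=15_000, seed=31, keep_null=True)
        exact = enumerate_permutation_null(matrix, range(matrix.n), 5)
        assert_pmfs_close(empirical_pmf(fl.null_sample), exact, fl.iterations)

    def test_pool_includes_all_factors(self):
        prof = make_simple_model(SimpleModelSpec(m=3))
        extra = BindingProfile("C", [GenomicInterval("chr9", 0, 100)])
        matrix = build_matrix(list(prof) + [extra])
        res = fl_test(matrix, "A", "B", iterations=100, seed=1)
        assert res.method == "fl"
        # a third factor's records dilute the pool, so not every record is
        # assigned: observed statistic stays that of the tested pair
        assert res.observed == 3.0

    def test_missing_factor_rejected(self):
        matrix = _simple_matrix(2)
        with pytest.raises(KeyError):
            fl_test(matrix, "A", "Z", iterations=10, seed=0)


class TestReproducibilityAndMerging:
    def test_identical_seed_gives_identical_result(self):
        matrix = _simple_matrix(5, singles=3)
        for fn in (permutation_test, independent_test, hybrid_test, fl_test):
            r1 = fn(matrix, "A", "B", iterations=2000, seed=42, keep_null=True)
            r2 = fn(matrix, "A", "B", iterations=2000, seed=42, keep_null=True)
            assert r1.exceed == r2.exceed
            assert np.array_equal(r1.null_sample, r2.null_sample)

    def test_partitioned_run_merges_exceed_counts(self):
        matrix = _simple_matrix(5, singles=3)
        merged = run_partitioned(hybrid_test, matrix, "A", "B",
                                 iterations=8000, partitions=4, seed=7)
        assert merged.iterations == 8000
        assert merged.p_hat == merged.exceed / 8000
        # partitioned estimate agrees with a single-stream run
        single = hybrid_test(matrix, "A", "B", iterations=8000, seed=7)
        tol = 4 * mc_se(max(single.p_hat, 1e-3), 8000)
        assert abs(merged.p_hat - single.p_hat) <= max(tol, 0.02)

    def test_merge_rejects_mismatched_tests(self):
        matrix = _simple_matrix(3)
        r1 = permutation_test(matrix, "A", "B", iterations=100, seed=0)
        r2 = independent_test(matrix, "A", "B", iterations=100, seed=0)
        with pytest.raises(ValueError):
            merge_results([r1, r2])

    def test_factor_order_invariance(self):
        matrix = _simple_matrix(4, singles=2)
        for fn in (permutation_test, independent_test, hybrid_test, fl_test):
            ab = fn(matrix, "A", "B", iterations=20_000, seed=3)
            ba = fn(matrix, "B", "A", iterations=20_000, seed=4)
            tol = 3 * (mc_se(max(ab.p_hat, 1e-3), 20_000) + mc_se(max(ba.p_hat, 1e-3), 20_000))
            assert abs(ab.p_hat - ba.p_hat) <= tol, fn.__name__


class TestSurveyThenFull:
    def test_disjoint_pair_screened_out(self):
        a = BindingProfile("A", [GenomicInterval("chr1", 0, 10)])
        b = BindingProfile("B", [GenomicInterval("chr1", 100, 110)])
        matrix = build_matrix([a, b])
        res = survey_then_full(permutation_test, matrix, "A", "B",
                               survey_iters=50, full_iters=5000, seed=0)
        assert res.screened
        assert res.iterations == 50
        assert res.p_hat == 1.0

    def test_co_occurring_pair_gets_full_run(self):
        matrix = _simple_matrix(10)
        res = survey_then_full(hybrid_test, matrix, "A", "B",
                               survey_iters=100, full_iters=5000, seed=1)
        assert not res.screened
        assert res.iterations == 5000
        assert res.p_hat < 0.05

    def test_cutoff_one_always_runs_full(self):
        a = BindingProfile("A", [GenomicInterval("chr1", 0, 10)])
        b = BindingProfile("B", [GenomicInterval("chr1", 100, 110)])
        matrix = build_matrix([a, b])
        res = survey_then_full(permutation_test, matrix, "A", "B",
                               survey_iters=50, cutoff=1.0, full_iters=300, seed=0)
        assert not res.screened
        assert res.iterations == 300

    def test_zero_exceedance_rendering(self):
        matrix = _simple_matrix(40)
        res = fl_test(matrix, "A", "B", iterations=5000, seed=2)
        assert res.below_resolution
        assert res.format_p() == "< 2e-04"


class TestCoLocalizationIndex:
    def test_ratio_and_log_ratio(self):
        assert ci_index(10, 10) == 1.0
        assert ci_index(10, 10, mode="log-ratio") == 0.0
        assert ci_index(20, 10) == 2.0

    def test_zero_resampled_count_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ci_index(10, 0)

    def test_distribution_depends_little_on_singleton_fraction(self):
        # 40 overlapped pairs with 10 vs 1000 singletons per factor: the CI
        # distribution is dominated by the absolute number of overlaps, so
        # the two distributions should nearly coincide
        samples = {}
        for singles in (10, 1000):
            matrix = _simple_matrix(40, singles=singles)
            samples[singles] = ci_distribution(matrix, "A", "B", iterations=5000, seed=7)
        ks = ks_2samp(samples[10], samples[1000])
        assert ks.statistic < 0.05
        assert np.median(samples[10]) == np.median(samples[1000])
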