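import numpy as np
import pytest

from pvhist import (
    DesignInfo,
    FeatureMatrix,
    PermutationNullSummary,
    PermutationPlan,
    count_distinct_assignments,
    generate_null_histograms,
    hc_threshold,
    permutation_hc_threshold,
    permutation_qc_threshold,
    qc_threshold,
    two_sample_t,
    paired_t,
)
from pvhist.permutation import _rank_combination, _unrank_combination
from pvhist.simulate import simulate_scenario


class TestCountDistinctAssignments:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(scheme="group_label", n1=3, n2=3), 10),
            (dict(scheme="group_label", n1=10, n2=10), 92_378),
            (dict(scheme="sign_flip", k=3), 4),
            (dict(scheme="group_label", n1=1, n2=1), 1),
            (dict(scheme="group_label", n1=2, n2=5), 21),
            (dict(scheme="sign_flip", k=1), 1),
        ],
    )
    def test_counts(self, kwargs, expected):
        assert count_distinct_assignments(**kwargs) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            count_distinct_assignments("group_label", n1=0, n2=3)
        with pytest.raises(ValueError):
            count_distinct_assignments("coin_flip", n1=1, n2=1)


class TestCombinationRanking:
    def test_rank_unrank_roundtrip(self):
        from itertools import combinations
        from math import comb

        n, k = 8, 3
        for rank, c in enumerate(combinations(range(n), k)):
            assert _unrank_combination(rank, n, k) == c
            assert _rank_combination(c, n) == rank
        assert rank + 1 == comb(n, k)


class TestGroupLabelScheme:
    def test_exhaustive_three_per_group(self, small_matrix, two_group_design):
        plan = PermutationPlan("group_label", B=10, seed=None, percentile=0.9)
        s = generate_null_histograms(small_matrix, two_group_design, two_sample_t, plan)
        assert s.B == 10
        assert s.plan.exhaustive is True
        assert s.plan.distinct_available == 10
        # exhaustive mode consumes no randomness: identical reruns
        s2 = generate_null_histograms(small_matrix, two_group_design, two_sample_t, plan)
        assert np.array_equal(s.first_bin_counts, s2.first_bin_counts)
        assert np.array_equal(s.max_bin_counts, s2.max_bin_counts)

    def test_single_feature_conservation(self):
        rng = np.random.default_rng(1)
        X = FeatureMatrix.from_arrays(rng.normal(size=(12, 1)))
        d = DesignInfo(group=("A",) * 6 + ("B",) * 6)
        plan = PermutationPlan("group_label", B=50, seed=0)
        s = generate_null_histograms(X, d, two_sample_t, plan)
        assert np.all(s.first_bin_counts <= 1)
        assert np.all(s.max_bin_counts == 1)

    def test_seeded_reproducibility_and_seed_stability(self):
        out = simulate_scenario("low_power", seed=4, m=300, n=6, pi0=1.0)
        plan_a = PermutationPlan("group_label", B=500, seed=101)
        s_a = generate_null_histograms(out.X, out.d, two_sample_t, plan_a)
        s_a2 = generate_null_histograms(out.X, out.d, two_sample_t, plan_a)
        assert np.array_equal(s_a.first_bin_counts, s_a2.first_bin_counts)

        s_b = generate_null_histograms(
            out.X, out.d, two_sample_t, PermutationPlan("group_label", B=500, seed=202)
        )
        for thr_a, thr_b in [
            (s_a.qc_threshold_perm, s_b.qc_threshold_perm),
            (s_a.hc_threshold_perm, s_b.hc_threshold_perm),
        ]:
            assert abs(thr_a - thr_b) / max(thr_a, thr_b) < 0.15

    def test_row_relabelling_never_alters_values(self, small_matrix, two_group_design):
        seen = []

        def spy_test(X, d):
            seen.append(X.values)
            return two_sample_t(X, d)

        plan = PermutationPlan("group_label", B=10, percentile=0.9)
        generate_null_histograms(small_matrix, two_group_design, spy_test, plan)
        for vals in seen:
            assert vals is small_matrix.values  # rows re-labelled, data untouched


class TestSignFlipScheme:
    def test_three_pairs_insufficient_for_95th_percentile(self, paired_design):
        X = FeatureMatrix.from_arrays(np.random.default_rng(0).normal(size=(6, 30)))
        plan = PermutationPlan("sign_flip", B=100, percentile=0.95)
        with pytest.raises(ValueError, match=r"only 4 distinct.*at least 20"):
            generate_null_histograms(X, paired_design, paired_t, plan)

    def test_exhaustive_enumeration_of_sign_vectors(self):
        rng = np.random.default_rng(2)
        k = 6
        groups, pairs = [], []
        for i in range(k):
            groups += ["A", "B"]
            pairs += [f"p{i}", f"p{i}"]
        X = FeatureMatrix.from_arrays(rng.normal(size=(2 * k, 40)))
        d = DesignInfo(group=tuple(groups), pair_id=tuple(pairs))
        plan = PermutationPlan("sign_flip", B=32, percentile=0.9)
        s = generate_null_histograms(X, d, paired_t, plan)
        assert s.plan.exhaustive is True
        assert s.B == 2 ** (k - 1) == s.plan.distinct_available


class TestPercentileThresholds:
    def make_summary(self, first, percentile=0.95):
        first = np.asarray(first)
        plan = PermutationPlan("group_label", B=len(first), percentile=percentile)
        return PermutationNullSummary(
            first_bin_counts=first,
            max_bin_counts=first,
            hc_threshold_perm=0.0,
            qc_threshold_perm=0.0,
            percentile=percentile,
            plan=plan,
        )

    def test_constant_counts(self):
        s = self.make_summary([7] * 30)
        assert permutation_hc_threshold(s) == 7.0

    def test_linear_interpolation(self):
        s = self.make_summary(np.arange(1, 101))
        assert permutation_hc_threshold(s) == pytest.approx(95.05)
        assert permutation_qc_threshold(s) == pytest.approx(95.05)


class TestIndependenceLimit:
    def test_thresholds_converge_to_analytic(self):
        # under independent null features the permutation thresholds agree
        # with the exact binomial thresholds up to Monte-Carlo error
        out = simulate_scenario("low_power", seed=21, m=1000, n=10, pi0=1.0)
        plan = PermutationPlan("group_label", B=200, seed=3)
        s = generate_null_histograms(out.X, out.d, two_sample_t, plan)
        assert abs(s.hc_threshold_perm - hc_threshold(1000)) <= 6
        assert abs(s.qc_threshold_perm - qc_threshold(1000)) <= 7

    def test_correlation_raises_qc_threshold(self):
        # a correlated block inflates max-bin null counts well past the
        # independence bound
        out = simulate_scenario(
            "correlated", seed=8, m=536, n=12, rho=0.75, block_size=500
        )
        plan = PermutationPlan("group_label", B=200, seed=5)
        s = generate_null_histograms(out.X, out.d, two_sample_t, plan)
        assert s.qc_threshold_perm > qc_threshold(536)
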