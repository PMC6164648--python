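import numpy as np
import pytest

from pvhist import (
    DesignInfo,
    FeatureMatrix,
    ks_uniform,
    paired_t,
    read_design_tsv,
    read_matrix_tsv,
    two_sample_t,
    wilcoxon_rank_sum,
)
from pvhist.simulate import simulate_scenario, write_scenario_tsvs


def matrix_from_groups(a: np.ndarray, b: np.ndarray):
    X = FeatureMatrix.from_arrays(np.vstack([a, b]))
    d = DesignInfo(group=("A",) * a.shape[0] + ("B",) * b.shape[0])
    return X, d


class TestFeatureMatrixValidation:
    def test_rejects_missing_values(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing value"):
            FeatureMatrix.from_arrays(vals)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError, match="at least 2"):
            FeatureMatrix.from_arrays(np.ones((1, 3)))

    def test_design_needs_two_groups_of_two(self):
        d = DesignInfo(group=("A", "A", "A", "B"))
        with pytest.raises(ValueError, match=">= 2 samples"):
            d.two_group_masks()
        with pytest.raises(ValueError, match="exactly two"):
            DesignInfo(group=("A", "B", "C", "A")).two_group_masks()


class TestTwoSampleT:
    def test_pooled_closed_form(self):
        # t = -1.2247 with df = 4 for (0,1,2) vs (1,2,3)
        X, d = matrix_from_groups(
            np.array([[0.0], [1.0], [2.0]]), np.array([[1.0], [2.0], [3.0]])
        )
        assert two_sample_t(X, d).values[0] == pytest.approx(0.2878, abs=2e-4)

    def test_identical_groups_give_p_one(self):
        a = np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]])
        X, d = matrix_from_groups(a, a.copy())
        assert np.allclose(two_sample_t(X, d).values, 1.0)

    def test_degenerate_constant_feature(self):
        a = np.full((3, 2), 2.0)
        b = np.full((3, 2), 2.0)
        b[:, 1] = 5.0  # constant but different mean
        X, d = matrix_from_groups(a, b)
        p = two_sample_t(X, d).values
        assert p[0] == 1.0 and p[1] == 0.0

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        X, d = matrix_from_groups(rng.normal(size=(4, 30)), rng.normal(size=(5, 30)))
        d_swapped = DesignInfo(group=tuple("B" if g == "A" else "A" for g in d.group))
        assert np.allclose(two_sample_t(X, d).values, two_sample_t(X, d_swapped).values)

    def test_pooled_equals_welch_for_equal_variance_groups(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 25))
        b = a + 0.7  # identical sample variances, equal sizes
        X, d = matrix_from_groups(a, b)
        pooled = two_sample_t(X, d, "pooled").values
        welch = two_sample_t(X, d, "welch").values
        assert np.allclose(pooled, welch, atol=1e-10)

    def test_null_pvalues_uniform(self):
        # seeded replications of an all-null experiment should pass KS
        failures = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X, d = matrix_from_groups(
                rng.normal(size=(10, 10_000)), rng.normal(size=(10, 10_000))
            )
            if ks_uniform(two_sample_t(X, d)).p_value < 0.01:
                failures += 1
        assert failures <= 2

    def test_unknown_variance_mode(self):
        rng = np.random.default_rng(2)
        X, d = matrix_from_groups(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            two_sample_t(X, d, variance="robust")


class TestPairedT:
    @pytest.fixture
    def paired(self):
        def build(diffs: np.ndarray):
            k = diffs.shape[0]
            base = np.random.default_rng(5).normal(size=(k, diffs.shape[1]))
            rows, groups, pairs = [], [], []
            for i in range(k):
                rows += [base[i], base[i] + diffs[i]]
                groups += ["A", "B"]
                pairs += [f"p{i}", f"p{i}"]
            X = FeatureMatrix.from_arrays(np.vstack(rows))
            return X, DesignInfo(group=tuple(groups), pair_id=tuple(pairs))

        return build

    def test_constant_nonzero_differences(self, paired):
        X, d = paired(np.ones((3, 1)))
        assert paired_t(X, d).values[0] == 0.0

    def test_zero_mean_differences(self, paired):
        X, d = paired(np.array([[-1.0], [0.0], [1.0]]))
        assert paired_t(X, d).values[0] == pytest.approx(1.0)

    def test_closed_form(self, paired):
        # differences (1,2,3): t = 2*sqrt(3), df = 2
        X, d = paired(np.array([[1.0], [2.0], [3.0]]))
        assert paired_t(X, d).values[0] == pytest.approx(0.0742, abs=2e-4)

    def test_bad_pairing_rejected(self):
        d = DesignInfo(group=("A", "A", "B", "B"), pair_id=("p1", "p1", "p2", "p2"))
        X = FeatureMatrix.from_arrays(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="pair"):
            paired_t(X, d)


class TestWilcoxonRankSum:
    def test_extreme_separation_exact(self):
        # complete separation at n1 = n2 = 3: 2 of C(6,3)=20 orderings
        X, d = matrix_from_groups(
            np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]])
        )
        assert wilcoxon_rank_sum(X, d).values[0] == pytest.approx(0.1)

    def test_identical_groups(self):
        a = np.array([[1.0], [2.0], [3.0]])
        X, d = matrix_from_groups(a, a.copy())
        assert wilcoxon_rank_sum(X, d).values[0] == pytest.approx(1.0, abs=0.05)

    def test_discrete_support_minimum(self):
        # at n1 = n2 = 3 the attainable two-sided p-values have minimum 0.1
        rng = np.random.default_rng(3)
        X, d = matrix_from_groups(rng.normal(size=(3, 500)), rng.normal(size=(3, 500)))
        p = wilcoxon_rank_sum(X, d).values
        assert p.min() >= 0.1 - 1e-12
        assert len(set(np.round(p, 6))) >= 4

    def test_validity_at_tiny_n(self):
        # valid but not proper: P(p <= t) <= t for every t on the support
        rng = np.random.default_rng(13)
        X, d = matrix_from_groups(rng.normal(size=(3, 4000)), rng.normal(size=(3, 4000)))
        p = wilcoxon_rank_sum(X, d).values
        for t in (0.1, 0.2, 0.4, 0.7):
            assert (p <= t + 1e-12).mean() <= t + 3 * np.sqrt(t * (1 - t) / 4000)


class TestOutputsAreProbabilities:
    @pytest.mark.parametrize("test_name", ["ttest", "welch", "wilcoxon"])
    def test_random_matrices(self, test_name):
        from pvhist.feature_tests import TEST_REGISTRY

        rng = np.random.default_rng(17)
        fn = TEST_REGISTRY[test_name]
        for _ in range(25):
            n1, n2 = rng.integers(2, 8, size=2)
            m = int(rng.integers(1, 40))
            X, d = matrix_from_groups(
                rng.normal(size=(n1, m)) * rng.uniform(0.1, 5),
                rng.normal(size=(n2, m)),
            )
            p = fn(X, d).values
            assert np.all((p >= 0) & (p <= 1))


class TestTSVRoundTrip:
    def test_matrix_and_design_reconciled_by_sample_id(self, tmp_path):
        out = simulate_scenario("low_power", seed=0, m=12, n=3)
        paths = write_scenario_tsvs(out, tmp_path, prefix="toy")
        X = read_matrix_tsv(paths["matrix"])
        assert np.allclose(X.values, out.X.values)
        assert X.feature_ids == out.X.feature_ids

        # shuffle design rows: matching must go through sample_id
        design = (tmp_path / "toy_design.tsv").read_text().splitlines()
        shuffled = [design[0]] + design[1:][::-1]
        (tmp_path / "shuffled.tsv").write_text("\n".join(shuffled) + "\n")
        d = read_design_tsv(tmp_path / "shuffled.tsv", X.sample_ids)
        assert d.group == out.d.group

    def test_missing_sample_errors(self, tmp_path):
        (tmp_path / "d.tsv").write_text("sample_id\tgroup\ns1\tA\n")
        with pytest.raises(ValueError, match="missing sample_ids"):
            read_design_tsv(tmp_path / "d.tsv", ("s1", "s2"))
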