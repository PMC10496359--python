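import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coevotest import (
    CorrelationMatrix,
    PairTestResult,
    bh_adjust,
    classify_pair,
    compare_correlations,
    disjoint_pairing_control,
    fisher_z,
    overlap_expectation,
    run_pairwise_scan,
)

corr_strategy = st.floats(min_value=-0.99, max_value=0.99)


class TestFisherZ:
    def test_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)  # (1/2) ln 3
        assert fisher_z(-0.9) == pytest.approx(-1.472219, abs=1e-6)

    @given(corr_strategy)
    @settings(deadline=None)
    def test_odd_and_increasing(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-14)
        assert fisher_z(min(r + 0.005, 0.995)) >= fisher_z(r)

    def test_rejects_unit_correlation(self):
        with pytest.raises(ValueError, match=">= 1"):
            fisher_z(1.0)


class TestCompareCorrelations:
    def test_equal_correlations_null(self):
        z, p = compare_correlations(0.37, 0.37, 20, 100)
        assert z == 0.0
        assert p == 1.0

    def test_worked_value(self):
        z, p = compare_correlations(0.5, 0.0, 15, 4817)
        assert z == pytest.approx(1.9005, abs=2e-4)
        assert p == pytest.approx(0.0574, abs=2e-4)

    @given(corr_strategy, corr_strategy)
    @settings(deadline=None)
    def test_antisymmetric_in_roles(self, a, b):
        z1, p1 = compare_correlations(a, b, 15, 15)
        z2, p2 = compare_correlations(b, a, 15, 15)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    @given(corr_strategy, corr_strategy, st.integers(4, 50), st.integers(4, 5000))
    @settings(deadline=None, max_examples=50)
    def test_p_invariant_to_exchanging_samples(self, a, b, n1, n2):
        _, p1 = compare_correlations(a, b, n1, n2)
        _, p2 = compare_correlations(b, a, n2, n1)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="exceed 3"):
            compare_correlations(0.1, 0.2, 3, 100)


class TestBHAdjust:
    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_step_up_hand_case(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_order_preserving(self):
        p = [0.04, 0.001, 0.2, 0.01]
        adj = bh_adjust(p)
        assert np.argsort(adj).tolist() == np.argsort(p).tolist()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _result(cor_m, cor_e, p_adj=0.01, p_m=0.001, p_e=0.001):
    return PairTestResult(
        trait_i="a",
        trait_j="b",
        cor_m=cor_m,
        cor_e=cor_e,
        z_m=np.arctanh(cor_m),
        z_e=np.arctanh(cor_e),
        z_stat=0.0,
        p_raw=p_adj,
        p_adj=p_adj,
        cor_m_nonzero_p=p_m,
        cor_e_nonzero_p=p_e,
    )


class TestClassifyPair:
    def test_strengthened_same_sign(self):
        assert classify_pair(_result(0.3, 0.8)) == "strengthened"

    def test_weakened_same_sign(self):
        assert classify_pair(_result(0.8, 0.3)) == "weakened"

    def test_reversed_both_nonzero(self):
        assert classify_pair(_result(0.5, -0.5)) == "reversed"

    def test_sign_flip_only_core_nonzero_is_strengthened(self):
        assert classify_pair(_result(-0.1, 0.6, p_m=0.8, p_e=0.001)) == "strengthened"

    def test_sign_flip_only_corm_nonzero_is_weakened(self):
        assert classify_pair(_result(0.6, -0.1, p_m=0.001, p_e=0.8)) == "weakened"

    def test_not_significant_above_fdr(self):
        assert classify_pair(_result(0.5, -0.5, p_adj=0.2)) == "not_significant"

    def test_sign_flip_neither_nonzero_unclassified(self):
        assert classify_pair(_result(0.1, -0.1, p_m=0.8, p_e=0.8)) == "unclassified"


def _random_corr(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n + 5, n))
    return CorrelationMatrix(np.corrcoef(x, rowvar=False))


class TestPairwiseScan:
    def test_identical_matrices_nothing_significant(self):
        m = _random_corr(10, 0)
        scan = run_pairwise_scan(m, m, 15, 5000)
        assert scan.n_significant == 0
        assert scan.counts["not_significant"] == 45

    @pytest.mark.parametrize("n_traits,n_pairs", [(220, 24090), (24, 276)])
    def test_pair_counts(self, n_traits, n_pairs):
        m = CorrelationMatrix(np.eye(n_traits))
        scan = run_pairwise_scan(m, m, 15, 5000)
        assert scan.n_pairs == n_pairs

    def test_categories_partition_significant(self):
        m = _random_corr(12, 1)
        e = _random_corr(12, 2)
        scan = run_pairwise_scan(m, e, 15, 100000, fdr=0.2)
        c = scan.counts
        assert (
            c["strengthened"] + c["weakened"] + c["reversed"] + c["unclassified"]
            == scan.n_significant
        )
        assert scan.n_significant + c["not_significant"] == scan.n_pairs

    def test_trait_mismatch_lists_difference(self):
        m = CorrelationMatrix(np.eye(3), ["a", "b", "c"])
        e = CorrelationMatrix(np.eye(3), ["a", "b", "d"])
        with pytest.raises(ValueError, match="c.*d"):
            run_pairwise_scan(m, e, 15, 100)

    def test_scan_matches_scalar_api(self):
        m = _random_corr(6, 3)
        e = _random_corr(6, 4)
        scan = run_pairwise_scan(m, e, 15, 500)
        row = scan.results.iloc[7]
        z, p = compare_correlations(row.cor_e, row.cor_m, 15, 500)
        assert row.z_stat == pytest.approx(z)
        assert row.p_raw == pytest.approx(p)
        assert np.allclose(bh_adjust(scan.results.p_raw), scan.results.p_adj)


class TestDisjointPairing:
    def test_pair_count_and_all_significant(self):
        traits = [f"t{i}" for i in range(220)]
        all_pairs = {(a, b) for i, a in enumerate(traits) for b in traits[i + 1 :]}
        fr = disjoint_pairing_control(traits, all_pairs, n_repeats=5, seed=0)
        assert np.allclose(fr, 1.0)

    def test_none_significant(self):
        traits = [f"t{i}" for i in range(10)]
        fr = disjoint_pairing_control(traits, set(), n_repeats=8, seed=1)
        assert np.allclose(fr, 0.0)

    def test_odd_count_drops_one(self):
        traits = [f"t{i}" for i in range(11)]
        all_pairs = {(a, b) for i, a in enumerate(traits) for b in traits[i + 1 :]}
        fr = disjoint_pairing_control(traits, all_pairs, n_repeats=3, seed=2)
        assert np.allclose(fr, 1.0)  # 5 pairs per repeat, all significant

    def test_seed_reproducible(self):
        traits = [f"t{i}" for i in range(20)]
        sig = {("t0", "t1"), ("t2", "t3")}
        a = disjoint_pairing_control(traits, sig, 50, seed=5)
        b = disjoint_pairing_control(traits, sig, 50, seed=5)
        assert np.array_equal(a, b)

    def test_rejects_zero_repeats(self):
        with pytest.raises(ValueError):
            disjoint_pairing_control(["a", "b"], set(), 0, seed=0)


class TestOverlapExpectation:
    @staticmethod
    def _universe(n=20):
        return [(f"t{i}", f"t{j}") for i in range(n) for j in range(i + 1, n)][:20]

    def test_set_a_equals_universe_p_one(self):
        u = self._universe()
        res = overlap_expectation(u, u[:5], u, n_draws=200, seed=0)
        assert res.p_value == 1.0
        assert np.all(res.null_counts == 5)

    def test_disjoint_sets_p_one(self):
        u = self._universe()
        res = overlap_expectation(u[:5], u[10:15], u, n_draws=200, seed=0)
        assert res.observed == 0
        assert res.p_value == 1.0

    def test_null_mean_matches_hypergeometric(self):
        u = self._universe(20)  # 20 pairs in the universe
        res = overlap_expectation(u[:5], u[:5], u, n_draws=4000, seed=3)
        # overlap of a uniform 5-subset with a fixed 5-subset of 20 elements
        expect = stats.hypergeom(len(u), 5, 5).mean()  # = k^2 / N = 1.25
        assert expect == pytest.approx(25 / 20)
        assert res.null_counts.mean() == pytest.approx(expect, abs=0.1)
        assert res.observed == 5

    def test_oversized_draw_rejected(self):
        u = self._universe()
        with pytest.raises(ValueError, match="universe"):
            overlap_expectation(u[:2], u, u[:5], n_draws=10)
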