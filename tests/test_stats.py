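"""Paired statistical protocol: routing, signed-rank, t, chi-square."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import glycodiary as gd
from glycodiary.errors import DegenerateDataError
from glycodiary.stats import benjamini_hochberg, compare_paired, wilcoxon_signed_rank

from _oracles import wilcoxon_enumeration_p


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        # all six differences positive: p = 2/2^6 = 0.03125
        w, p, degen = wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5, 6]))
        assert w == 21.0
        assert p == pytest.approx(2 / 64)
        assert not degen

    def test_antisymmetric_pair(self):
        _, p, _ = wilcoxon_signed_rank(np.array([3.0, -3.0]))
        assert p == 1.0

    def test_all_zero_differences_degenerate(self):
        w, p, degen = wilcoxon_signed_rank(np.zeros(10))
        assert (w, p, degen) == (0.0, 1.0, True)

    def test_zero_differences_dropped(self):
        w1, p1, _ = wilcoxon_signed_rank(np.array([1.0, 2, 3, 0, 0]))
        w2, p2, _ = wilcoxon_signed_rank(np.array([1.0, 2, 3]))
        assert (w1, p1) == (w2, p2)

    @pytest.mark.parametrize("trial", range(25))
    def test_exact_equals_enumeration_oracle(self, trial):
        """DP-computed exact p equals full 2^n sign enumeration (with ties)."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 13))
        d = rng.integers(-5, 6, size=n).astype(float)  # integer diffs force ties
        w_o, p_o = wilcoxon_enumeration_p(d)
        if (d != 0).sum() == 0:
            return
        w, p, _ = wilcoxon_signed_rank(d)
        assert w == pytest.approx(w_o)
        assert p == pytest.approx(p_o, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=11)
           .filter(lambda d: any(v != 0 for v in d)))
    def test_exact_p_equals_enumeration_property(self, diffs):
        """Property: DP exact p == 2^n enumeration for any small instance."""
        d = np.asarray(diffs, dtype=float)
        w_o, p_o = wilcoxon_enumeration_p(d)
        w, p, _ = wilcoxon_signed_rank(d)
        assert w == pytest.approx(w_o)
        assert p == pytest.approx(p_o, rel=1e-12)

    def test_tie_free_exact_matches_scipy(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.3, 1.0, 15)  # continuous -> tie-free
        w, p, _ = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="exact", alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_n_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.2, 1.0, 60)
        _, p, _ = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=False,
                           alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestPairedT:
    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateDataError):
            gd.paired_t(np.array([3.0, 4, 5]), np.array([1.0, 2, 3]))

    def test_reversed_sample_gives_p_one(self):
        x = np.array([1.0, 2, 3, 4, 6])
        t, p = gd.paired_t(x, x[::-1])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_eight_pairs(self):
        x = np.array([5.1, 4.8, 6.2, 5.5, 4.9, 5.8, 6.0, 5.2])
        y = np.array([4.9, 4.5, 5.9, 5.6, 4.6, 5.3, 5.8, 5.1])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_hand = 2 * sps.t.sf(abs(t_hand), df=len(d) - 1)
        t, p = gd.paired_t(x, y)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-12)


class TestChiSquare:
    def test_identical_distributions(self):
        # sex split 79/45 in both arms: statistic 0, p = 1.000
        stat, p, dof = gd.chi_square(np.array([[79, 45], [79, 45]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert dof == 1

    def test_perfect_separation_2x2(self):
        stat, _, _ = gd.chi_square(np.array([[10, 0], [0, 10]]))
        assert stat == pytest.approx(20.0)

    def test_transpose_and_permutation_invariance(self, rng):
        table = rng.integers(5, 40, size=(3, 4)).astype(float)
        stat, p, _ = gd.chi_square(table)
        stat_t, p_t, _ = gd.chi_square(table.T)
        assert stat_t == pytest.approx(stat)
        perm = table[rng.permutation(3)][:, rng.permutation(4)]
        stat_p, _, _ = gd.chi_square(perm)
        assert stat_p == pytest.approx(stat)

    def test_degenerate_margin(self):
        with pytest.raises(DegenerateDataError):
            gd.chi_square(np.array([[5, 5], [0, 0]]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=4, max_size=4),
           st.integers(min_value=0, max_value=10_000))
    def test_statistic_invariant_to_ordering_property(self, cells, perm_seed):
        """Property: chi-square is invariant to row/column reordering."""
        table = np.array(cells, dtype=float).reshape(2, 2)
        r = np.random.default_rng(perm_seed)
        perm = table[r.permutation(2)][:, r.permutation(2)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small expected counts are fine here
            assert gd.chi_square(perm)[0] == pytest.approx(gd.chi_square(table)[0])


class TestRouting:
    def test_large_normal_sample_routes_to_t(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(0, 1, 248)
            hits += gd.route(x)[0] == "paired_t"
        assert hits >= 18

    def test_zero_inflated_routes_to_wilcoxon(self, rng):
        x = rng.lognormal(3, 1, 248)
        x[rng.random(248) < 0.6] = 0.0
        assert gd.route(x)[0] == "wilcoxon"

    def test_constant_variable_warns_to_wilcoxon(self):
        with pytest.warns(UserWarning):
            assert gd.route(np.ones(30))[0] == "wilcoxon"

    def test_too_few_values(self):
        with pytest.raises(DegenerateDataError):
            gd.route(np.array([1.0, 2.0]))

    def test_food_groups_forced_to_wilcoxon(self, rng):
        x = rng.normal(10, 1, 40)
        y = rng.normal(10, 1, 40)
        res = compare_paired("grp", x, y, force_wilcoxon=True)
        assert res.test == "wilcoxon"
        assert res.route_reason == "forced"


def test_compare_paired_pairwise_deletion(rng):
    x = rng.normal(0, 1, 30)
    y = rng.normal(0, 1, 30)
    x[[3, 7]] = np.nan
    res = compare_paired("v", x, y)
    assert res.n_pairs == 28
    assert 0 <= res.p_value <= 1


def test_benjamini_hochberg_bounds_and_order():
    p = np.array([0.001, 0.02, 0.04, 0.8, 0.5])
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-15).all()
    assert (adj <= 1.0).all()
    # adjusted values preserve the p-value ordering (monotone step-up)
    assert np.argsort(adj).tolist() == np.argsort(p).tolist()


def test_type_one_error_quick_null_check(rng):
    """Under exchangeable null pairs, both routes reject near alpha."""
    rejections = 0
    trials = 200
    for i in range(trials):
        r = np.random.default_rng(i)
        x, y = r.normal(0, 1, 30), r.normal(0, 1, 30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = compare_paired("v", x, y)
        rejections += res.p_value <= 0.05
    assert 0.01 <= rejections / trials <= 0.10
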