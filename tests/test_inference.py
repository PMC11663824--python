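import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snarcpipe.inference import (
    holm_correction,
    jonckheere_terpstra,
    jt_statistic,
    jzs_bf,
    one_sample_t,
    one_sample_t_from_summary,
    paired_t,
    pearson_cor,
    welch_t,
    welch_t_from_summary,
)


def exact_jt_p(groups):
    """Enumeration oracle: exact one-sided permutation p over all label assignments."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = [len(g) for g in groups]
    bounds = np.cumsum(sizes)[:-1]
    observed = jt_statistic(groups)
    seen = 0
    ge = 0
    for perm in set(itertools.permutations(pooled.tolist())):
        arr = np.array(perm)
        parts = np.split(arr, bounds)
        seen += 1
        if jt_statistic(parts) >= observed - 1e-12:
            ge += 1
    return ge / seen


class TestOneSampleT:
    def test_raw_data_matches_summary(self):
        rng = np.random.default_rng(1)
        x = rng.normal(-3.0, 5.0, 40)
        raw = one_sample_t(x, compute_bf=False)
        summ = one_sample_t_from_summary(
            x.mean(), x.std(ddof=1), len(x), compute_bf=False
        )
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)

    def test_mean_equals_mu0(self):
        res = one_sample_t([1.0, 2.0, 3.0], mu0=2.0, compute_bf=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_nonzero_mean_infinite_t(self):
        res = one_sample_t_from_summary(3.0, 0.0, 10)
        assert math.isinf(res.statistic) and res.statistic > 0
        assert res.p_value == 0.0

    def test_sidedness(self):
        two = one_sample_t([1.0, 2.0, 4.0], sidedness="two", compute_bf=False)
        less = one_sample_t([1.0, 2.0, 4.0], sidedness="less", compute_bf=False)
        greater = one_sample_t([1.0, 2.0, 4.0], sidedness="greater", compute_bf=False)
        assert less.p_value + greater.p_value == pytest.approx(1.0)
        assert two.p_value == pytest.approx(2 * greater.p_value)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])


class TestWelch:
    def test_hand_computed_example(self):
        res = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], compute_bf=False)
        assert res.statistic == pytest.approx(-math.sqrt(1.5), abs=1e-10)  # -1.2247
        assert res.df == pytest.approx(4.0, abs=1e-10)

    def test_identical_groups(self):
        res = welch_t([1.0, 2.0], [1.0, 2.0], compute_bf=False)
        assert res.statistic == pytest.approx(0.0)

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=15),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=15),
    )
    @settings(max_examples=100, deadline=None)
    def test_df_bounds(self, a, b):
        av, bv = np.array(a), np.array(b)
        if av.std(ddof=1) == 0 and bv.std(ddof=1) == 0:
            return
        res = welch_t(a, b, compute_bf=False)
        n1, n2 = len(a), len(b)
        assert min(n1, n2) - 1 - 1e-9 <= res.df <= n1 + n2 - 2 + 1e-9


class TestPairedT:
    def test_identical_pairs(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], compute_bf=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_mean_differences(self):
        res = paired_t([2.0, 2.0, 2.0], [1.0, 2.0, 3.0], compute_bf=False)
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2*sqrt(3)
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], compute_bf=False)
        assert res.statistic == pytest.approx(2 * math.sqrt(3), abs=1e-10)
        assert res.df == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])


class TestJzsBf:
    def test_null_favored_at_t_zero(self):
        for n in (10, 50, 200):
            assert jzs_bf(0.0, n) < 1.0

    def test_monotone_in_abs_t(self):
        bfs = [jzs_bf(t, 40) for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_symmetry_two_sided(self):
        assert jzs_bf(2.5, 30) == pytest.approx(jzs_bf(-2.5, 30), rel=1e-6)

    def test_one_sided_halves_sum_to_two_sided(self):
        # truncated priors are renormalized, so the two directed BFs average
        # to the two-sided BF
        t, n = 1.7, 25
        two = jzs_bf(t, n, sidedness="two")
        less = jzs_bf(t, n, sidedness="less")
        greater = jzs_bf(t, n, sidedness="greater")
        assert 0.5 * (less + greater) == pytest.approx(two, rel=1e-6)
        assert greater > two > less

    def test_two_sample_uses_effective_n(self):
        bf_two_sample = jzs_bf(2.0, 20, 20)
        bf_one_sample_eff = jzs_bf(2.0, 10)
        # same effective n=10 but different df: values close, not equal
        assert bf_two_sample == pytest.approx(bf_one_sample_eff, rel=0.2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            jzs_bf(math.inf, 10)
        with pytest.raises(ValueError):
            jzs_bf(1.0, 1)
        with pytest.raises(ValueError):
            jzs_bf(1.0, 10, sidedness="both")

    def test_bf_attached_to_t_tests(self):
        res = one_sample_t_from_summary(-3.43, 8.63, 112)
        assert res.bf10 == pytest.approx(jzs_bf(res.statistic, 112), rel=1e-9)


class TestPearsonCor:
    def test_perfect_correlation(self):
        res = pearson_cor([1.0, 2.0, 3.0], [2.0, 4.0, 6.0], compute_bf=False)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_r(self):
        # x=(1,2,3), y=(1,2,4): r = 3 / sqrt(2 * 14/3) = 0.98198
        res = pearson_cor([1.0, 2.0, 3.0], [1.0, 2.0, 4.0], compute_bf=False)
        assert res.statistic == pytest.approx(3 / math.sqrt(28 / 3), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_cor([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bf_less_than_one_for_null_r_large_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=130)
        y = rng.normal(size=130)
        res = pearson_cor(x, y)
        assert res.bf10 is not None and res.bf10 < 1.0


class TestJonckheereTerpstra:
    def test_maximal_statistic_and_enumeration_p(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        assert jt_statistic(groups) == 12.0
        assert exact_jt_p(groups) == pytest.approx(1 / 90)
        res = jonckheere_terpstra(groups, n_perm=20000, seed=0)
        assert res.t_jt == 12.0
        assert res.p_value == pytest.approx(1 / 90, abs=0.004)

    def test_ties_counted_half(self):
        assert jt_statistic([[1.0], [1.0]]) == 0.5

    def test_add_one_estimator_never_zero(self):
        res = jonckheere_terpstra([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                                  n_perm=50, seed=1)
        assert res.p_value >= 1 / 51

    def test_reversed_strong_trend_large_p(self):
        groups = [[10.0, 11.0, 12.0], [5.0, 6.0, 7.0], [1.0, 2.0, 3.0]]
        res = jonckheere_terpstra(groups, n_perm=500, seed=2)
        assert res.p_value > 0.9

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(60):
            groups = [rng.normal(size=6) for _ in range(3)]
            ps.append(jonckheere_terpstra(groups, n_perm=200, rng=rng).p_value)
        ps = np.array(ps)
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.2).mean() < 0.5

    def test_enumeration_convergence_small_patterns(self):
        rng = np.random.default_rng(7)
        n_perm = 3000
        for sizes in [(1, 1, 2), (2, 2, 2), (1, 3, 3), (2, 3, 3), (1, 2, 4)]:
            groups = [rng.normal(size=s) for s in sizes]
            p_exact = exact_jt_p(groups)
            res = jonckheere_terpstra(groups, n_perm=n_perm, seed=11)
            se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
            assert abs(res.p_value - p_exact) <= 4 * se + 2 / n_perm

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1.0, 2.0]])


class TestHolm:
    def test_hand_computed_stepdown(self):
        adjusted = holm_correction([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adjusted, [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_correction([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(holm_correction([1.0, 1.0, 1.0]), 1.0)

    @given(
        ps=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_adjusted_ge_raw_and_monotone(self, ps):
        adjusted = holm_correction(ps)
        raw = np.array(ps)
        assert np.all(adjusted >= raw - 1e-12)
        assert np.all(adjusted <= 1.0)
        order = np.argsort(raw)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_correction([0.5, 1.2])
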