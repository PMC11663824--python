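import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snarcpipe.bootstrap import (
    BootstrapClassification,
    chi_square_independence,
    classify,
    fisher_exact_rxc,
    h0_bootstrap,
    prevalence_table,
)
from snarcpipe.simulate import DIGITS
from tests.conftest import balanced_trials, linear_drt_trials


def chi_square_oracle(table):
    """Closed-form Pearson chi-square, written independently of the module."""
    obs = np.asarray(table, dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


class TestClassify:
    def test_rule(self):
        assert classify(-9.0, -5.0, 5.0) == "reliable"
        assert classify(9.0, -5.0, 5.0) == "reliable_reverse"
        assert classify(0.0, -5.0, 5.0) == "unreliable"

    def test_boundary_equality_is_unreliable(self):
        assert classify(-5.0, -5.0, 5.0) == "unreliable"
        assert classify(5.0, -5.0, 5.0) == "unreliable"

    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            BootstrapClassification("p", "PJ", "SNARC", 0.0, 1.0, -1.0, 10, "unreliable")


class TestH0Bootstrap:
    def test_degenerate_constant_rts(self):
        trials = balanced_trials(n_per_side=3)  # all RTs 500
        results = h0_bootstrap(trials, n_iter=50, seed=0)
        for c in results:
            assert c.q05 == c.q95 == 0.0
            assert c.empirical_slope == pytest.approx(0.0)
            assert c.label == "unreliable"

    def test_pj_returns_snarc_and_marc(self):
        trials = linear_drt_trials(slope=-9.0)
        results = h0_bootstrap(trials, n_iter=100, seed=1)
        assert {c.effect for c in results} == {"SNARC", "MARC"}
        assert all(c.task == "PJ" for c in results)

    def test_mc_returns_categorical_snarc_only(self):
        trials = linear_drt_trials(task="MC", slope=-9.0)
        results = h0_bootstrap(trials, n_iter=100, seed=1)
        assert [c.effect for c in results] == ["SNARC"]
        # categorical empirical slope: -9 * (7.5 - 2.5)
        assert results[0].empirical_slope == pytest.approx(-45.0, abs=1e-9)

    def test_strong_effect_with_small_noise_is_reliable(self):
        rng = np.random.default_rng(5)
        trials = linear_drt_trials(slope=-20.0, n_per_side=20)
        trials = trials.copy()
        trials["rt_ms"] = trials["rt_ms"] + rng.normal(0, 5.0, len(trials))
        results = h0_bootstrap(trials, n_iter=500, seed=2)
        snarc = next(c for c in results if c.effect == "SNARC")
        assert snarc.label == "reliable"

    def test_reproducible_with_seed(self):
        trials = linear_drt_trials(slope=-5.0)
        a = h0_bootstrap(trials, n_iter=200, seed=42)
        b = h0_bootstrap(trials, n_iter=200, seed=42)
        assert a == b

    def test_missing_digit_rejected(self):
        trials = linear_drt_trials()
        trials = trials[trials["digit"] != 4]
        with pytest.raises(ValueError, match="digit 4"):
            h0_bootstrap(trials, n_iter=10, seed=0)

    def test_null_coverage_small_scale(self):
        # reduced version of the calibration acceptance check
        rng = np.random.default_rng(17)
        n_out = 0
        n_participants = 60
        for i in range(n_participants):
            trials = balanced_trials(
                pid=f"p{i}", n_per_side=20,
                rt_fn=lambda d, s, k: rng.normal(600.0, 100.0),
            )
            res = h0_bootstrap(trials, n_iter=1000, seed=int(rng.integers(2**32)))
            snarc = next(c for c in res if c.effect == "SNARC")
            if snarc.label != "unreliable":
                n_out += 1
        rate = n_out / n_participants
        assert 0.0 <= rate <= 0.25  # loose at this n; tight bound in acceptance

    def test_power_monotone_in_slope_magnitude(self):
        rng = np.random.default_rng(23)
        rates = []
        for slope in (0.0, -5.0, -10.0, -20.0):
            n_rel = 0
            for i in range(25):
                trials = linear_drt_trials(pid=f"p{i}", slope=slope, n_per_side=20)
                trials = trials.copy()
                trials["rt_ms"] += rng.normal(0, 80.0, len(trials))
                res = h0_bootstrap(trials, n_iter=400, seed=int(rng.integers(2**32)))
                snarc = next(c for c in res if c.effect == "SNARC")
                if snarc.label == "reliable":
                    n_rel += 1
            rates.append(n_rel / 25)
        assert rates[0] <= rates[2] + 0.1
        assert rates[-1] >= rates[0]
        assert rates[-1] >= 0.8


class TestPrevalenceTable:
    def test_paper_style_percentages(self):
        cls = []
        labels = ["reliable"] * 74 + ["reliable_reverse"] * 6 + ["unreliable"] * 50
        for i, lab in enumerate(labels):
            emp = {"reliable": -9.0, "reliable_reverse": 9.0, "unreliable": 0.0}[lab]
            cls.append(
                BootstrapClassification(f"p{i}", "PJ", "SNARC", emp, -5.0, 5.0, 10, lab)
            )
        groups = {f"p{i}": "German" for i in range(130)}
        table = prevalence_table(cls, groups)
        assert table.counts.loc["German", "reliable"] == 74
        assert table.percentages.loc["German", "reliable"] == pytest.approx(56.92, abs=0.01)
        assert table.counts.sum(axis=1).loc["German"] == 130

    def test_participant_in_no_group_rejected(self):
        cls = [BootstrapClassification("p0", "PJ", "SNARC", 0.0, -1.0, 1.0, 10, "unreliable")]
        with pytest.raises(ValueError, match="no group"):
            prevalence_table(cls, {})

    def test_empty_group_row_rejected(self):
        cls = [BootstrapClassification("p0", "PJ", "SNARC", 0.0, -1.0, 1.0, 10, "unreliable")]
        with pytest.raises(ValueError, match="empty group"):
            prevalence_table(cls, {"p0": "A"}, group_order=["A", "B"])


class TestChiSquare:
    def test_hand_computed_2x2(self):
        res = chi_square_independence([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20.0 / 3.0, abs=1e-10)
        assert res.df == 1

    def test_identical_rows_zero(self):
        res = chi_square_independence([[5, 5, 5], [5, 5, 5]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            table = rng.integers(1, 60, size=(3, 3))
            res = chi_square_independence(table)
            assert res.statistic == pytest.approx(chi_square_oracle(table), abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[1, -2], [3, 4]])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [1, 2]])


class TestFisherExact:
    def test_2x2_against_scipy_oracle(self):
        table = [[1, 9], [11, 3]]
        res = fisher_exact_rxc(np.array(table))
        _, p_scipy = stats.fisher_exact(table)
        assert res.extra["method"] == "enumeration"
        assert res.p_value == pytest.approx(p_scipy, abs=1e-10)
        assert res.p_value == pytest.approx(0.002759, abs=5e-6)

    def test_identical_rows_equal_margins_p_one(self):
        res = fisher_exact_rxc(np.array([[4, 4], [4, 4]]))
        assert res.p_value == pytest.approx(1.0)

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            table = rng.integers(1, 8, size=(2, 3))
            exact = fisher_exact_rxc(table, method="enumeration")
            mc = fisher_exact_rxc(table, method="monte_carlo", n_mc=20000, seed=3)
            se = math.sqrt(exact.p_value * (1 - exact.p_value) / 20000)
            assert abs(mc.p_value - exact.p_value) <= 3 * se + 1e-4

    def test_3x3_enumeration_matches_mc(self):
        table = np.array([[5, 1, 2], [1, 6, 1], [2, 1, 5]])
        exact = fisher_exact_rxc(table, method="enumeration")
        mc = fisher_exact_rxc(table, method="monte_carlo", n_mc=50000, seed=4)
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 50000)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 1e-4

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc(np.array([[0, 0], [1, 2]]))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc(np.array([[1.5, 2.0], [1.0, 1.0]]))
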