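import math

import numpy as np
import pytest

from pvsignal.contingency import FourfoldTable
from pvsignal.dispro import (BCPNNPriors, SignalCriteria, chi_square,
                             consistency_check, evaluate_signal, ic_estimate,
                             ic_mc, prr_estimate, ror_estimate,
                             round_half_away)

T_HAND = FourfoldTable(10, 90, 100, 9900)


class TestROR:
    def test_symmetric_table_gives_unity_with_log_symmetric_ci(self):
        est = ror_estimate(FourfoldTable(25, 25, 25, 25))
        assert est.value == pytest.approx(1.0)
        assert est.lo * est.hi == pytest.approx(1.0)  # symmetric about 1 on log scale

    def test_hand_arithmetic_example(self):
        est = ror_estimate(T_HAND)
        assert est.value == pytest.approx(11.0)
        # ln-scale Wald: se = sqrt(1/10 + 1/90 + 1/100 + 1/9900)
        assert round_half_away(est.lo) == 5.56
        assert round_half_away(est.hi) == 21.76

    def test_zero_cell_is_undefined_value_not_exception(self):
        est = ror_estimate(FourfoldTable(0, 100, 100, 9800))
        assert not est.defined and est.reason == "zero cell"

    def test_odds_ratio_invariant_under_transpose(self):
        assert ror_estimate(T_HAND).value == pytest.approx(ror_estimate(T_HAND.transpose()).value)


class TestPRR:
    def test_equal_proportions_give_unity(self):
        assert prr_estimate(FourfoldTable(10, 90, 100, 900)).value == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        est = prr_estimate(T_HAND)
        assert est.value == pytest.approx(10.0)
        assert round_half_away(est.lo) == 5.38
        assert round_half_away(est.hi) == 18.58

    def test_zero_target_cell_undefined(self):
        assert not prr_estimate(FourfoldTable(0, 100, 10, 9890)).defined
        assert not prr_estimate(FourfoldTable(10, 90, 0, 9900)).defined

    def test_prr_approaches_ror_for_rare_events(self):
        # event proportions < 1% in both arms -> relative difference < 1%
        t = FourfoldTable(30, 9970, 50, 19950)
        ror, prr = ror_estimate(t).value, prr_estimate(t).value
        assert abs(ror - prr) / ror < 0.01


class TestChiSquare:
    def test_perfect_independence_gives_zero(self):
        assert chi_square(FourfoldTable(10, 90, 100, 900)) == pytest.approx(0.0)

    def test_matches_textbook_pearson_formula(self):
        # independent reference: chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 10, 90, 100, 9900
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi_square(T_HAND) == pytest.approx(expected)

    def test_invariant_under_transpose(self):
        assert chi_square(T_HAND) == pytest.approx(chi_square(T_HAND.transpose()))

    def test_zero_marginal_undefined(self):
        assert chi_square(FourfoldTable(0, 0, 100, 9900)) is None


class TestIC:
    def test_independent_large_table_near_zero(self):
        # a == (a+b)(a+c)/N exactly, all cells large
        t = FourfoldTable(100, 9900, 9900, 980100)
        assert abs(ic_estimate(t).value) < 0.05

    def test_interval_brackets_point(self):
        est = ic_estimate(T_HAND)
        assert est.lo < est.value < est.hi

    def test_defined_on_zero_cells(self):
        est = ic_estimate(FourfoldTable(0, 100, 50, 9850))
        assert est.value is not None and est.value < 0

    def test_closed_form_matches_monte_carlo_mean(self):
        closed = ic_estimate(T_HAND).value
        mc_mean, _, _ = ic_mc(T_HAND, n_samples=200_000, seed=42)
        assert abs(closed - mc_mean) < 0.02

    def test_monte_carlo_is_deterministic_given_seed(self):
        assert ic_mc(T_HAND, seed=7) == ic_mc(T_HAND, seed=7)

    def test_monte_carlo_converges_to_closed_form(self):
        closed = ic_estimate(T_HAND).value
        coarse = abs(ic_mc(T_HAND, n_samples=1000, seed=3)[0] - closed)
        fine = abs(ic_mc(T_HAND, n_samples=64_000, seed=3)[0] - closed)
        assert fine < 0.02
        assert fine < coarse + 0.02  # shrinking MC error, up to noise

    def test_closed_form_within_3_mc_standard_errors_on_random_battery(self):
        rng = np.random.default_rng(2024)
        n_samples = 20_000
        for _ in range(100):
            a = int(rng.integers(1, 60))
            b = int(rng.integers(10, 2000))
            c = int(rng.integers(1, 500))
            d = int(rng.integers(1000, 200_000))
            t = FourfoldTable(a, b, c, d)
            closed = ic_estimate(t).value
            mean, q_lo, q_hi = ic_mc(t, n_samples=n_samples, seed=int(rng.integers(2**31)))
            se = max((q_hi - q_lo) / 3.92 / math.sqrt(n_samples), 1e-4)
            assert abs(closed - mean) < 3 * se + 5e-3

    def test_point_estimates_strictly_increase_in_a(self):
        prev = None
        for a in (5, 10, 20, 40):
            t = FourfoldTable(a, 500, 300, 50_000)
            trio = (ror_estimate(t).value, prr_estimate(t).value, ic_estimate(t).value)
            if prev is not None:
                assert all(x > y for x, y in zip(trio, prev))
            prev = trio


class TestEvaluateSignal:
    def test_fewer_than_min_cases_blocks_signal_despite_huge_ror(self):
        t = FourfoldTable(2, 10, 5, 100_000)
        res = evaluate_signal(t)
        assert not res.flags["min_cases_met"]
        assert res.ror.defined and res.ror.lo > 1
        assert not res.signal

    def test_lower_ci_at_or_below_one_blocks_signal(self):
        t = FourfoldTable(10, 90, 95, 905)  # ROR ~ 1.06, CI spans 1
        res = evaluate_signal(t)
        assert res.ror.lo <= 1
        assert not res.signal

    def test_strong_injected_association_signals(self):
        # a = 50 where independence expects ~5 in a 100k-report database
        t = FourfoldTable(50, 950, 500, 98_500)
        res = evaluate_signal(t)
        assert all(res.flags.values()) and res.signal

    def test_undefined_estimator_counts_as_not_positive(self):
        t = FourfoldTable(0, 1000, 500, 98_500)
        res = evaluate_signal(t)
        assert not res.flags["ror_positive"] and not res.signal

    def test_classical_prr_rule_switch(self):
        t = FourfoldTable(50, 950, 500, 98_500)
        res = evaluate_signal(t, SignalCriteria(classical_prr_rule=True))
        assert res.flags["prr_positive"]  # PRR ~ 10 >= 2 and chi2 >> 4
        assert res.signal


class TestConsistencyCheck:
    def test_round_trip_recovers_a_background_reproducing_rounded_values(self):
        t = FourfoldTable(60, 3940, 800, 995_200)
        ror, prr = ror_estimate(t), prr_estimate(t)
        printed = tuple(round_half_away(v) for v in (ror.value, ror.lo, ror.hi, prr.value))
        res = consistency_check(t.a, t.drug_total, printed, c_max=5000)
        assert res.ok
        solved = FourfoldTable(t.a, t.b, res.c, res.d)
        r2, p2 = ror_estimate(solved), prr_estimate(solved)
        assert (round_half_away(r2.value), round_half_away(r2.lo),
                round_half_away(r2.hi), round_half_away(p2.value)) == printed

    def test_corrupted_printed_values_are_infeasible(self):
        res = consistency_check(147, 5670, (400.0, 34.3, 47.78, 39.46), decimals=(2, 1, 2, 2))
        assert not res.ok
        assert res.c is None and res.achieved  # diagnostic with closest values


class TestPriorsAndRounding:
    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            BCPNNPriors(alpha1=0.0)

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            SignalCriteria(min_cases=0)

    def test_round_half_away_from_zero(self):
        assert round_half_away(2.5, 0) == 3.0
        assert round_half_away(-2.5, 0) == -3.0
        assert round_half_away(0.125, 2) == 0.13  # exact binary half rounds away
        assert round_half_away(-0.125, 2) == -0.13
        assert round_half_away(39.464) == 39.46
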