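"""Unit tests for the core state machine: probability curve, attenuation,
sampling conventions, loss accounting, and the trial transition."""

import dataclasses
from fractions import Fraction

import numpy as np
import pytest

from iccs import (
    BudgetError,
    ConstantPolicy,
    Decision,
    InvalidStateError,
    ModelParams,
    apply_losses,
    attenuated_loss_percent,
    climate_probability,
    initial_state,
    run_game,
    sample_damages,
    sample_disaster_type,
    sample_occurrence,
    step_trial,
)


def state_with_share(params, share):
    s = initial_state(params)
    s.cum_income = 10_000.0
    s.cum_mitigation_investment = share * 10_000.0
    return s


class TestClimateProbability:
    def test_zero_investment_forces_certain_disaster(self, params):
        assert climate_probability(initial_state(params), params) == 1.0

    @pytest.mark.parametrize("k", [1.0, 2.0, 3.0])
    def test_full_investment_leaves_residual_probability(self, params, k):
        # share 1: p = 1 - m for any exponent (exact rational evaluation)
        p = climate_probability(
            state_with_share(params.replace(probability_exponent=k), 1.0), params
        )
        assert p == pytest.approx(float(1 - Fraction(85, 100)), abs=1e-15)

    def test_half_share_cubic_matches_rational_arithmetic(self):
        params = ModelParams.cubic()
        expected = 1 - Fraction(85, 100) * Fraction(1, 2) ** 3  # = 0.89375
        p = climate_probability(state_with_share(params, 0.5), params)
        assert p == pytest.approx(float(expected), abs=1e-15)

    def test_zero_cumulative_income_is_invalid_state(self, params):
        s = initial_state(params)
        s.cum_income = 0.0
        with pytest.raises(InvalidStateError):
            climate_probability(s, params)

    def test_monotone_decreasing_in_mitigation(self, params):
        shares = np.linspace(0, 1, 21)
        ps = [climate_probability(state_with_share(params, x), params) for x in shares]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestAttenuatedLossPercent:
    def test_five_property_purchases_in_36_trials(self, params):
        # the insured property-loss percentage after 5 purchases: (5/36)*100
        r = attenuated_loss_percent(5, params, "property")
        assert r == pytest.approx(float(Fraction(500, 36)), abs=1e-12)

    def test_no_purchases_means_full_attenuation(self, params):
        assert attenuated_loss_percent(0, params, "injury") == 0.0

    @pytest.mark.parametrize(
        "mode,cap", [("injury", 10.0), ("fatality", 20.0), ("property", 50.0)]
    )
    def test_cap_binds_at_max_purchases(self, params, mode, cap):
        # brute-force: min((100/36)*c, cap) over every reachable count
        for c in range(params.total_trials + 1):
            expected = min(100.0 * c / 36.0, cap)
            assert attenuated_loss_percent(c, params, mode) == pytest.approx(expected)

    def test_negative_count_rejected(self, params):
        with pytest.raises(ValueError):
            attenuated_loss_percent(-1, params, "injury")


class TestSampling:
    def test_certain_probability_always_occurs(self, rng):
        assert all(sample_occurrence(1.0, rng) for _ in range(1000))

    def test_zero_probability_needs_exact_zero_draw(self, stub_rng):
        assert sample_occurrence(0.0, stub_rng([0.0]))
        assert not sample_occurrence(0.0, stub_rng([1e-12]))

    def test_occurrence_frequency_calibrated(self, rng):
        n = 20_000
        freq = sum(sample_occurrence(0.3, rng) for _ in range(n)) / n
        assert freq == pytest.approx(0.3, abs=0.01)

    def test_degenerate_type_distribution(self, rng, params):
        p = params.replace(disaster_type_probs=(1.0, 0.0, 0.0))
        assert all(sample_disaster_type(rng, p) == "cyclone" for _ in range(200))

    def test_threshold_ordering_cyclone_drought_flood(self, stub_rng, params):
        # single draw against cumulative 0.33 / 0.66 / 1.0 thresholds
        assert sample_disaster_type(stub_rng([0.10]), params) == "cyclone"
        assert sample_disaster_type(stub_rng([0.50]), params) == "drought"
        assert sample_disaster_type(stub_rng([0.90]), params) == "flood"

    def test_drought_never_damages_property(self, rng, params):
        for _ in range(500):
            assert not sample_damages("drought", rng, params)[2]

    def test_zero_damage_probs_are_harmless(self, rng, params):
        p = params.replace(damage_probs=(0.0, 0.0, 0.0))
        assert sample_damages("cyclone", rng, p) == (False, False, False)

    def test_drought_consumes_two_damage_draws(self, stub_rng, params):
        r = stub_rng([0.5, 0.5, 0.5])
        sample_damages("drought", r, params)
        assert r.i == 2
        r = stub_rng([0.5, 0.5, 0.5])
        sample_damages("flood", r, params)
        assert r.i == 3


class TestApplyLosses:
    def test_no_damage_leaves_state_unchanged(self, params):
        s = initial_state(params)
        before = dataclasses.replace(s)
        _, losses, pcts = apply_losses(s, (False, False, False), params)
        assert s == before
        assert losses == (0.0, 0.0, 0.0) and pcts == (0.0, 0.0, 0.0)

    def test_uninsured_property_damage_halves_wealth(self, params):
        s = initial_state(params)
        w = s.property_wealth
        _, losses, _ = apply_losses(s, (False, False, True), params)
        assert s.property_wealth == pytest.approx(w / 2)
        assert losses[2] == pytest.approx(w / 2)

    def test_insured_property_damage_after_five_purchases(self, params):
        # hand arithmetic: 13.888...% of 100,000 = 13,888.9; remainder 86,111.1
        s = initial_state(params)
        s.property_wealth = 100_000.0
        s.insurance_purchase_counts = (0, 0, 5)
        s.insured_this_trial = (False, False, True)
        _, losses, pcts = apply_losses(s, (False, False, True), params)
        assert losses[2] == pytest.approx(13_888.9, abs=0.05)
        assert s.property_wealth == pytest.approx(86_111.1, abs=0.05)
        assert pcts[2] == pytest.approx(100 * 5 / 36)

    def test_income_losses_share_base_and_persist(self, params):
        s = initial_state(params)
        income = s.annual_income
        _, losses, _ = apply_losses(s, (True, True, False), params)
        assert losses[0] == pytest.approx(0.125 * income)
        assert losses[1] == pytest.approx(0.25 * income)
        assert s.annual_income == pytest.approx(income * (1 - 0.125 - 0.25))
        assert s.uninvested_cash == pytest.approx(-(0.125 + 0.25) * income)


class TestStepTrial:
    def test_zero_investment_means_certain_disaster(self, params, rng):
        s = initial_state(params)
        for _ in range(5):
            s, out = step_trial(s, Decision(0.0), rng, params)
            assert out.probability == 1.0 and out.occurred

    def test_full_mitigation_linear_probability(self, params, rng):
        s = initial_state(params)
        for _ in range(10):
            s, out = step_trial(s, Decision(s.annual_income), rng, params)
            assert out.probability == pytest.approx(0.15)

    def test_unaffordable_decision_reports_shortfall(self, params, rng):
        s = initial_state(params)
        with pytest.raises(BudgetError, match="shortfall"):
            step_trial(s, Decision(s.annual_income + 100.0), rng, params)

    def test_purchase_counts_and_coverage_current_window(self, params, stub_rng):
        s = initial_state(params)
        s2, _ = step_trial(
            s, Decision(0.0, buy_health=True), stub_rng([0.5, 0.5, 0.5, 0.5, 0.5]), params
        )
        assert s2.insurance_purchase_counts == (1, 0, 0)
        assert s2.insured_this_trial == (False, False, False)  # cleared after trial

    def test_next_window_coverage_shifts_one_trial(self, stub_rng):
        params = ModelParams(coverage_window="next")
        s = initial_state(params)
        s2, out1 = step_trial(
            s, Decision(0.0, buy_property=True), stub_rng([0.0, 0.9, 0.5, 0.5, 0.4]), params
        )
        # property damage this trial is NOT covered by this trial's purchase
        assert out1.damages[2] and out1.loss_percent_applied[2] == 50.0
        assert s2.insured_this_trial == (False, False, True)
        s3, out2 = step_trial(
            s2, Decision(0.0), stub_rng([0.0, 0.9, 0.5, 0.5, 0.4]), params
        )
        # next trial the purchase from trial 1 attenuates the loss
        assert out2.damages[2]
        assert out2.loss_percent_applied[2] == pytest.approx(100 / 36)

    def test_input_state_not_mutated(self, params, rng):
        s = initial_state(params)
        frozen = dataclasses.replace(s)
        step_trial(s, Decision(100.0, buy_life=True), rng, params)
        assert s == frozen


class TestRunGame:
    def test_zero_trials_rejected_at_params_validation(self):
        with pytest.raises(ValueError):
            ModelParams(total_trials=0)

    def test_zero_investment_policy_logs_all_occurrences(self, params):
        log = run_game(ConstantPolicy(0.0), params, 7)
        assert len(log) == 36
        assert log.table["occurred"].sum() == 36
        assert (log.table["p"] == 1.0).all()

    def test_same_seed_same_log(self, params):
        from iccs import RandomPolicy

        a = run_game(RandomPolicy(), params, 42)
        b = run_game(RandomPolicy(), params, 42)
        assert a.table.equals(b.table)

    def test_different_seeds_differ(self, params):
        from iccs import RandomPolicy

        a = run_game(RandomPolicy(), params, 1)
        b = run_game(RandomPolicy(), params, 2)
        assert not a.table.equals(b.table)

    def test_error_carries_trial_index(self, params):
        import pandas as pd

        from iccs import ScriptedPolicy

        rows = pd.DataFrame(
            {
                "mitigation_amount": [0.0] * 6 + [1e9] + [0.0] * 29,
                "buy_health": 0,
                "buy_life": 0,
                "buy_property": 0,
            }
        )
        with pytest.raises(BudgetError, match="trial 7"):
            run_game(ScriptedPolicy(rows, params), params, 0)
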