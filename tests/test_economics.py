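"""Time and micro-costing models: worked cells, perspectives, comparative statics."""

import dataclasses

import pytest

import rosecost as rc
from rosecost.economics import CostInputs, OperationalInputs


class TestTime:
    @pytest.mark.parametrize(
        "passes, t_pass, expected",
        [(3.0, 2.0, 6.0), (0.0, 17.0, 0.0), (1.724138, 9.0, 15.517241)],
    )
    def test_sampling_time(self, passes, t_pass, expected):
        assert rc.sampling_time(passes, t_pass) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "t_setup, t_sample, expected", [(30.0, 6.0, 36.0), (0.0, 11.0, 11.0), (4.0, 6.0, 10.0)]
    )
    def test_procedure_time(self, t_setup, t_sample, expected):
        oper = OperationalInputs(t_setup=t_setup, t_pass_fixed=2.0, t_pass_rose=9.0)
        assert rc.procedure_time(oper, t_sample) == expected

    def test_warns_when_rose_pass_faster_than_fixed(self):
        with pytest.warns(UserWarning):
            OperationalInputs(t_setup=10.0, t_pass_fixed=5.0, t_pass_rose=2.0)


class TestRates:
    def test_societal_rates(self, complex_base_inputs):
        _, _, cost = complex_base_inputs
        assert rc.variable_rate(cost, rc.FIXED) == 280.0  # 260 + patient 20
        assert rc.variable_rate(cost, rc.ROSE) == 380.0  # 260 + 100 + 20

    def test_provider_perspective_drops_patient_wage(self, complex_base_inputs):
        _, _, cost = complex_base_inputs
        provider = dataclasses.replace(cost, perspective=rc.PROVIDER)
        assert rc.variable_rate(provider, rc.FIXED) == 260.0
        assert rc.variable_rate(provider, rc.ROSE) == 360.0

    def test_overrides_replace_pre_patient_sum(self, complex_base_inputs):
        _, _, cost = complex_base_inputs
        pinned = dataclasses.replace(cost, fixed_rate_override=130.0, rose_rate_override=130.0)
        assert rc.variable_rate(pinned, rc.FIXED) == 150.0  # patient wage still added
        assert rc.variable_rate(pinned, rc.ROSE) == 150.0


class TestCosts:
    def test_fixed_complex_cost_per_procedure_is_558(self, complex_base_inputs):
        tech, oper, cost = complex_base_inputs
        perf = rc.performance(tech, rc.FIXED)
        # (36/60)*280 + 300 + 3*30
        assert rc.cost_per_procedure(perf, oper, cost, rc.FIXED) == pytest.approx(558.0)

    def test_rose_complex_cost_per_procedure(self, complex_base_inputs):
        tech, oper, cost = complex_base_inputs
        perf = rc.performance(tech, rc.ROSE)
        assert rc.cost_per_procedure(perf, oper, cost, rc.ROSE) == pytest.approx(640.0)

    def test_all_zero_costs_give_zero(self, complex_base_inputs):
        tech, oper, _ = complex_base_inputs
        free = CostInputs(0.0, 0.0, 0.0, 0.0, 0.0)
        perf = rc.performance(tech, rc.FIXED)
        assert rc.cost_per_procedure(perf, oper, free, rc.FIXED) == 0.0

    def test_cost_per_case(self):
        assert rc.cost_per_case(558.0, 1.0 / 0.936) == pytest.approx(596.153846)
        assert rc.cost_per_case(640.0, 1.016667) == pytest.approx(650.67, abs=0.01)
        assert rc.cost_per_case(123.0, 1.0) == 123.0

    def test_cost_per_case_rejects_sub_unit_procedures(self):
        with pytest.raises(ValueError):
            rc.cost_per_case(100.0, 0.9)


class TestEvaluatePolicy:
    def test_complex_high_base_case(self, complex_base_inputs):
        tech, oper, cost = complex_base_inputs
        fixed = rc.evaluate_policy(tech, oper, cost, rc.FIXED)
        rose = rc.evaluate_policy(tech, oper, cost, rc.ROSE)
        assert fixed.cost_per_case == pytest.approx(596.15, abs=0.01)
        assert rose.cost_per_case == pytest.approx(650.67, abs=0.01)
        assert rc.cost_difference(rose, fixed) == pytest.approx(54.51, abs=0.01)
        # internal consistency of the bundle
        for outcome in (fixed, rose):
            assert outcome.t_procedure == pytest.approx(oper.t_setup + outcome.t_sample)
            assert outcome.cost_per_case == pytest.approx(
                outcome.cost_per_procedure * outcome.sampling.expected_procedures
            )
            assert outcome.cost_per_case >= outcome.cost_per_procedure

    def test_patient_wage_shifts_cost_upward(self, complex_base_inputs):
        tech, oper, cost = complex_base_inputs
        pricier = dataclasses.replace(cost, rate_patient=cost.rate_patient + 10.0)
        for protocol in (rc.FIXED, rc.ROSE):
            assert (
                rc.evaluate_policy(tech, oper, pricier, protocol).cost_per_case
                > rc.evaluate_policy(tech, oper, cost, protocol).cost_per_case
            )

    def test_cost_difference_rejects_swapped_arguments(self, complex_base_inputs):
        tech, oper, cost = complex_base_inputs
        fixed = rc.evaluate_policy(tech, oper, cost, rc.FIXED)
        rose = rc.evaluate_policy(tech, oper, cost, rc.ROSE)
        with pytest.raises(ValueError):
            rc.cost_difference(fixed, rose)

    def test_no_repeat_limit(self, complex_base_inputs):
        """With adequacy 1 the per-case cost collapses to the per-procedure cost."""
        _, oper, cost = complex_base_inputs
        tech = rc.TechnicalInputs(p=1.0, n_fixed=3)
        outcome = rc.evaluate_policy(tech, oper, cost, rc.FIXED)
        assert outcome.cost_per_case == pytest.approx(outcome.cost_per_procedure)


class TestComparativeStatics:
    """Directional effects of single parameters on the cost difference."""

    def _delta(self, cost, oper, tech):
        rose = rc.evaluate_policy(tech, oper, cost, rc.ROSE)
        fixed = rc.evaluate_policy(tech, oper, cost, rc.FIXED)
        return rc.cost_difference(rose, fixed)

    def test_fixed_cost_favors_rose_when_rose_more_adequate(self, complex_base_inputs):
        tech, oper, cost = complex_base_inputs
        assert rc.adequacy_rose(tech.p, tech.sp, tech.n_rose) > rc.adequacy_fixed(
            tech.p, tech.n_fixed
        )
        base = self._delta(cost, oper, tech)
        bumped = self._delta(dataclasses.replace(cost, cost_fixed=cost.cost_fixed + 1.0), oper, tech)
        assert bumped < base  # dDeltaTC/dc_fixed = N_proc^R - N_proc^F < 0

    def test_rose_pass_time_and_cytologist_rate_raise_delta(self, complex_base_inputs):
        tech, oper, cost = complex_base_inputs
        base = self._delta(cost, oper, tech)
        slower = dataclasses.replace(oper, t_pass_rose=oper.t_pass_rose + 1.0)
        assert self._delta(cost, slower, tech) > base
        pricier = dataclasses.replace(cost, rate_cytologist=cost.rate_cytologist + 1.0)
        assert self._delta(pricier, oper, tech) > base

    def test_setup_time_effect_follows_rate_weighted_repeats(self, complex_base_inputs):
        """d(dTC)/dt_setup = (rate_R N_proc^R - rate_F N_proc^F)/60.

        Longer setup favors ROSE exactly when its rate-weighted repeat burden
        is below the fixed protocol's; with equal hourly rates this reduces
        to A^R > A^F.
        """
        tech, oper, cost = complex_base_inputs

        def slope(c, t):
            longer = dataclasses.replace(oper, t_setup=oper.t_setup + 1.0)
            return self._delta(c, longer, t) - self._delta(c, oper, t)

        def predicted_sign(c, t):
            rose = rc.performance(t, rc.ROSE).expected_procedures
            fixed = rc.performance(t, rc.FIXED).expected_procedures
            return (
                rc.variable_rate(c, rc.ROSE) * rose - rc.variable_rate(c, rc.FIXED) * fixed
            )

        # complex low-success: fewer repeats dominate, setup favors ROSE
        low = dataclasses.replace(tech, p=0.3)
        assert predicted_sign(cost, low) < 0 and slope(cost, low) < 0
        # equal hourly rates (simple staffing) with A^R > A^F: always favors ROSE
        pinned = dataclasses.replace(cost, fixed_rate_override=130.0, rose_rate_override=130.0)
        assert slope(pinned, tech) < 0
        # complex high-success: ROSE's pricier hour outweighs its fewer repeats
        assert predicted_sign(cost, tech) > 0 and slope(cost, tech) > 0

    def test_units_round_trip(self, complex_base_inputs):
        """Computing the time-based cost in hours equals minutes/60 exactly."""
        tech, oper, cost = complex_base_inputs
        outcome = rc.evaluate_policy(tech, oper, cost, rc.ROSE)
        hours = outcome.t_procedure / 60.0
        assert outcome.cost_variable == pytest.approx(hours * rc.variable_rate(cost, rc.ROSE))
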