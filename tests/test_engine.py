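"""Cycle plans, arm propagation, scenario orchestration."""

import dataclasses

import pytest

from copdsim import (
    CostSchedule,
    RiskEquationSet,
    TreatmentSpec,
    UtilityMapping,
    build_cycle_plan,
    run_arm,
    run_comparison,
    run_scenario,
)
from copdsim.engine import scenario_config
from copdsim.synthetic import (
    SyntheticModelSpec,
    base_case_config,
    make_synthetic_equations,
    reference_profile,
)


class TestCyclePlan:
    def test_one_year_plan(self):
        plan = build_cycle_plan("1y")
        assert plan.lengths == (0.25, 0.25, 0.5)

    def test_five_year_plan(self):
        plan = build_cycle_plan("5y")
        assert plan.lengths == (0.25, 0.25) + (0.5,) * 9
        assert plan.total_years == pytest.approx(5.0)

    def test_lifetime_plan_truncates_final_cycle(self):
        plan = build_cycle_plan("lifetime", start_age=63.3, age_cap=100.0)
        assert plan.lengths[:2] == (0.25, 0.25)
        assert len(plan.lengths) == 2 + 73
        assert plan.lengths[2:-1] == (0.5,) * 72
        assert plan.lengths[-1] == pytest.approx(0.2)
        assert plan.total_years == pytest.approx(36.7)

    def test_unknown_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            build_cycle_plan("10y")

    def test_start_age_beyond_cap_rejected(self):
        with pytest.raises(ValueError):
            build_cycle_plan("lifetime", start_age=101.0, age_cap=100.0)

    def test_midpoints(self):
        plan = build_cycle_plan("1y")
        assert plan.midpoints() == [0.125, 0.375, 0.75]


def _free_arm(**kwargs):
    """No dynamics, no mortality, free care: isolates the accounting."""
    defaults = dict(
        profile=reference_profile(),
        treatment=TreatmentSpec("none", 0.0),
        eqs=RiskEquationSet.null(),
        schedule=CostSchedule(),
        plan=build_cycle_plan("1y"),
        discount_rate=0.0,
        utility=UtilityMapping.flat(1.0),
    )
    defaults.update(kwargs)
    return run_arm(**defaults)


class TestRunArm:
    def test_null_dynamics_qalys_equal_horizon_years(self):
        arm = _free_arm()
        assert arm.qalys == pytest.approx(1.0, abs=1e-12)
        assert arm.life_years == pytest.approx(1.0, abs=1e-12)
        assert arm.total_cost == 0.0

    def test_drug_cost_day_count_over_one_year(self):
        arm = _free_arm(treatment=TreatmentSpec("t", 33.50))
        assert arm.total_cost == pytest.approx(33.50 * 365.25 / 30, abs=1e-9)
        assert arm.total_cost == pytest.approx(407.86, abs=0.005)

    def test_discounting_reduces_totals(self):
        undisc = _free_arm(treatment=TreatmentSpec("t", 33.50))
        disc = _free_arm(treatment=TreatmentSpec("t", 33.50), discount_rate=0.035)
        assert disc.total_cost < undisc.total_cost
        assert disc.qalys < undisc.qalys

    def test_alive_fraction_non_increasing(self, base_config):
        arm = run_arm(
            base_config.profile,
            base_config.comparator,
            base_config.equations,
            base_config.schedule,
            base_config.plan(),
        )
        alive = [s.alive_fraction for s in arm.states]
        assert all(a >= b for a, b in zip(alive, alive[1:]))

    def test_qalys_bounded_by_discounted_life_years(self, base_config):
        arm = run_arm(
            base_config.profile,
            base_config.comparator,
            base_config.equations,
            base_config.schedule,
            base_config.plan(),
            utility=base_config.utility,
        )
        assert arm.qalys <= arm.life_years_discounted + 1e-12
        assert arm.life_years_discounted <= arm.life_years + 1e-12

    def test_unknown_accrual_rejected(self):
        with pytest.raises(ValueError, match="accrual"):
            _free_arm(accrual="end_of_cycle")

    def test_start_of_cycle_accrual_accrues_more(self, base_config):
        kw = dict(
            profile=base_config.profile,
            treatment=base_config.comparator,
            eqs=base_config.equations,
            schedule=base_config.schedule,
            plan=base_config.plan(),
        )
        half = run_arm(**kw, accrual="half_cycle")
        start = run_arm(**kw, accrual="start_of_cycle")
        assert start.life_years > half.life_years


class TestRunComparison:
    def test_identical_arms_give_zero_deltas(self, base_config):
        config = dataclasses.replace(
            base_config, intervention=base_config.comparator
        )
        comparison, arms = run_comparison(config)
        assert comparison.delta_cost == 0.0
        assert comparison.delta_qaly == 0.0
        assert arms["intervention"].qalys == arms["comparator"].qalys

    def test_reproducibility_bit_identical(self, base_config):
        c1, a1 = run_comparison(base_config)
        c2, a2 = run_comparison(base_config)
        assert c1 == c2
        assert a1["intervention"].costs == a2["intervention"].costs

    def test_horizon_nesting_one_year_prefix_of_five(self, base_config):
        """The 1-year run is exactly the first three cycles of the 5-year run."""
        one = run_comparison(dataclasses.replace(base_config, horizon="1y"))[1]
        five = run_comparison(dataclasses.replace(base_config, horizon="5y"))[1]
        for key in ("intervention", "comparator"):
            t1 = one[key].trajectory
            t5 = five[key].trajectory[: len(t1)]
            assert t1 == t5

    def test_longer_horizon_accumulates_more(self, base_config):
        one = run_comparison(dataclasses.replace(base_config, horizon="1y"))[1]
        five = run_comparison(dataclasses.replace(base_config, horizon="5y"))[1]
        life = run_comparison(dataclasses.replace(base_config, horizon="lifetime"))[1]
        for key in ("intervention", "comparator"):
            assert (
                one[key].moderate_exacs
                <= five[key].moderate_exacs
                <= life[key].moderate_exacs
            )
            assert one[key].life_years <= five[key].life_years <= life[key].life_years


class TestScenarios:
    def test_scenario_configs_differ_only_as_specified(self, base_config):
        base = scenario_config("base", base_config)
        a = scenario_config("A", base_config)
        c = scenario_config("C", base_config)
        assert a == dataclasses.replace(base, horizon="1y")
        assert c == dataclasses.replace(
            base,
            intervention=dataclasses.replace(
                base.intervention, effect_duration=1.0
            ),
        )

    def test_unknown_scenario_rejected(self, base_config):
        with pytest.raises(ValueError, match="scenario"):
            run_scenario("D", base_config)

    def test_qaly_gain_grows_with_horizon_under_persistent_effect(self, base_config):
        dq = {
            which: run_scenario(which, base_config)[0].delta_qaly
            for which in ("A", "B", "base")
        }
        assert dq["A"] <= dq["B"] <= dq["base"]

    def test_limited_effect_duration_gains_no_more_than_lifetime(self, base_config):
        config5 = dataclasses.replace(base_config, horizon="5y")
        lifetime_effect = run_comparison(config5)[0]
        short_effect = run_comparison(
            dataclasses.replace(
                config5,
                intervention=dataclasses.replace(
                    config5.intervention, effect_duration=1.0
                ),
            )
        )[0]
        assert short_effect.delta_qaly <= lifetime_effect.delta_qaly


class TestTreatmentEffectInEngine:
    def test_fixed_offset_gives_constant_rate_ratio(self):
        """With only FEV1 driving the exacerbation equation, a persistent
        FEV1 offset yields the closed-form rate ratio every cycle."""
        import math

        profile = reference_profile()
        eqs = make_synthetic_equations(
            SyntheticModelSpec(
                fev1_decline=60.0, exac_log_slope_per_ml=-0.01, fev1_ref_ml=1000.0
            )
        )
        plan = build_cycle_plan("5y")
        kw = dict(profile=profile, eqs=eqs, schedule=CostSchedule(), plan=plan)
        treated = run_arm(treatment=TreatmentSpec("t", 0.0, effect_mean=92.17), **kw)
        control = run_arm(treatment=TreatmentSpec("c", 0.0), **kw)
        expected = math.exp(-0.01 * 92.17)
        for st_t, st_c in zip(treated.states[1:], control.states[1:]):
            assert st_t.annual_moderate_rate / st_c.annual_moderate_rate == (
                pytest.approx(expected, rel=1e-10)
            )
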