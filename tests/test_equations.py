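"""Risk-equation evaluation, state advancement and rate conversions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copdsim import (
    DiseaseState,
    EquationSpec,
    PatientProfile,
    RiskEquationSet,
    advance_state,
    annual_to_cycle,
    baseline_state,
    cycle_survival,
    evaluate_equation,
    resource_use,
)
from copdsim.equations import MissingCovariateError
from copdsim.synthetic import SyntheticModelSpec, make_synthetic_equations


class TestEvaluateEquation:
    @pytest.mark.parametrize(
        "spec, covs, expected",
        [
            (EquationSpec("x"), {}, 0.0),
            (EquationSpec("x", intercept=1.0, coefficients={"x": 2.0}), {"x": 3.0}, 7.0),
            (EquationSpec("x", link="logit", coefficients={"x": 1.0}), {"x": 0.0}, 0.5),
            (EquationSpec("x", link="log", intercept=math.log(0.4)), {}, 0.4),
        ],
    )
    def test_linear_predictor_and_links(self, spec, covs, expected):
        assert evaluate_equation(spec, covs) == pytest.approx(expected, abs=1e-12)

    def test_missing_covariate_is_named(self):
        spec = EquationSpec("fev1", coefficients={"fibrinogen": 1.0})
        with pytest.raises(MissingCovariateError, match="fibrinogen"):
            evaluate_equation(spec, {"age": 60.0})

    def test_unknown_link_rejected(self):
        with pytest.raises(ValueError, match="link"):
            EquationSpec("x", link="probit")


class TestAdvanceState:
    def test_null_equations_are_identity_except_age(self, profile, state):
        new = advance_state(state, profile, RiskEquationSet.null(), 0.5)
        assert new.age == state.age + 0.5
        for f in ("fev1_ml", "fev1pp", "sgrq", "p_dyspnoea", "p_cough_sputum",
                  "walk_m", "annual_moderate_rate", "annual_severe_rate",
                  "alive_fraction"):
            assert getattr(new, f) == getattr(state, f)

    def test_zero_coefficient_change_equations_are_identity(self, profile, state):
        # explicit all-zero change-mode equations, identity links
        eqs = RiskEquationSet(
            equations={
                out: EquationSpec(out, link="identity", mode="change")
                for out in ("fev1", "moderate_exac_rate", "severe_exac_rate",
                            "dyspnoea", "cough_sputum", "walk", "sgrq")
            }
        )
        new = advance_state(state, profile, eqs, 0.5)
        assert new.fev1_ml == state.fev1_ml
        assert new.annual_moderate_rate == state.annual_moderate_rate
        assert new.sgrq == state.sgrq

    def test_pure_fev1_decline_scales_with_cycle(self, profile, state):
        # -30 mL per half-year = -60 mL annual change
        eqs = make_synthetic_equations(SyntheticModelSpec(fev1_decline=60.0))
        new = advance_state(state, profile, eqs, 0.5)
        assert state.fev1_ml - new.fev1_ml == pytest.approx(30.0, abs=1e-9)

    def test_log_link_gives_constant_rate_ratio(self, profile, state):
        spec = SyntheticModelSpec(
            exac_log_slope_per_ml=-0.01, fev1_ref_ml=state.fev1_ml
        )
        eqs = make_synthetic_equations(spec)
        import dataclasses

        shifted = dataclasses.replace(state, fev1_ml=state.fev1_ml + 92.17)
        a = advance_state(state, profile, eqs, 0.5)
        b = advance_state(shifted, profile, eqs, 0.5)
        ratio = b.annual_moderate_rate / a.annual_moderate_rate
        assert ratio == pytest.approx(math.exp(-0.9217), rel=1e-12)

    def test_sgrq_clamped_with_warning(self, profile, state, caplog):
        import logging

        logging.getLogger("copdsim.equations").setLevel(logging.WARNING)
        eqs = RiskEquationSet(
            equations={"sgrq": EquationSpec("sgrq", mode="direct", intercept=140.0)}
        )
        with caplog.at_level(logging.WARNING, logger="copdsim.equations"):
            new = advance_state(state, profile, eqs, 0.5)
        assert new.sgrq == 100.0
        assert any("sgrq" in r.message for r in caplog.records)

    def test_negative_rate_clamped_to_zero(self, profile, state):
        eqs = RiskEquationSet(
            equations={
                "moderate_exac_rate": EquationSpec(
                    "moderate_exac_rate", mode="direct", intercept=-1.0
                )
            }
        )
        new = advance_state(state, profile, eqs, 0.5)
        assert new.annual_moderate_rate == 0.0

    def test_rejects_nonpositive_cycle(self, profile, state):
        with pytest.raises(ValueError):
            advance_state(state, profile, RiskEquationSet.null(), 0.0)


class TestAnnualToCycle:
    def test_rate_scales_linearly(self):
        assert annual_to_cycle(0.50, 0.5, "rate") == pytest.approx(0.25)

    def test_probability_one_year_identity(self):
        assert annual_to_cycle(0.19, 1.0, "probability") == pytest.approx(0.19)

    def test_probability_out_of_range_errors(self):
        with pytest.raises(ValueError):
            annual_to_cycle(1.3, 0.5, "probability")

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError):
            annual_to_cycle(0.5, 0.5, "hazard")

    @given(p=st.floats(0.0, 1.0 - 1e-9), k=st.integers(2, 12))
    @settings(max_examples=100, deadline=None)
    def test_probability_composition_recovers_annual(self, p, k):
        """Composing k equal sub-year conversions as survival products
        reproduces the annual probability to 1e-12."""
        surv = 1.0
        for _ in range(k):
            surv *= 1.0 - annual_to_cycle(p, 1.0 / k, "probability")
        assert 1.0 - surv == pytest.approx(p, abs=1e-12)


class TestCycleSurvival:
    def test_no_equation_means_no_mortality(self, profile, state):
        assert cycle_survival(state, profile, RiskEquationSet.null(), 0.5) == 1.0

    def test_constant_hazard_closed_form(self, profile, state):
        eqs = make_synthetic_equations(SyntheticModelSpec(base_mortality_hazard=0.1))
        assert cycle_survival(state, profile, eqs, 0.5) == pytest.approx(
            math.exp(-0.05), rel=1e-12
        )

    def test_doubling_cycle_squares_survival(self, profile, state):
        eqs = make_synthetic_equations(SyntheticModelSpec(base_mortality_hazard=0.2))
        s1 = cycle_survival(state, profile, eqs, 1.0)
        s2 = cycle_survival(state, profile, eqs, 2.0)
        assert s2 == pytest.approx(s1**2, rel=1e-12)

    def test_logit_link_uses_annual_probability(self, profile, state):
        # annual death probability 0.19 over one year
        eqs = RiskEquationSet(
            equations={
                "survival": EquationSpec(
                    "survival", link="logit",
                    intercept=math.log(0.19 / 0.81),
                )
            }
        )
        assert cycle_survival(state, profile, eqs, 1.0) == pytest.approx(0.81)


class TestResourceUse:
    def test_no_equations_means_zero_counts(self, profile, state):
        counts = resource_use(state, profile, RiskEquationSet.null(), 0.5)
        assert all(v == 0.0 for v in counts.values())

    def test_constant_annual_visits_scale_with_cycle(self, profile, state):
        eqs = make_synthetic_equations(SyntheticModelSpec(office_visits_per_year=2.0))
        counts = resource_use(state, profile, eqs, 0.5)
        assert counts["office_visits"] == pytest.approx(1.0)

    def test_hospitalisations_track_severe_rate(self, profile, state):
        eqs = make_synthetic_equations(
            SyntheticModelSpec(hospitalisations_per_severe=1.0)
        )
        counts = resource_use(state, profile, eqs, 0.5)
        assert counts["hospitalisations"] == pytest.approx(
            state.annual_severe_rate * 0.5
        )


class TestDomainTypes:
    def test_profile_validates_ranges(self):
        with pytest.raises(ValueError):
            PatientProfile(sgrq0=120.0)
        with pytest.raises(ValueError):
            PatientProfile(fev1pp0=0.0)
        with pytest.raises(ValueError):
            PatientProfile(female=1.4)

    def test_bmi_category_constructor(self):
        p = PatientProfile.from_bmi_category("low")
        assert (p.bmi_low, p.bmi_high, p.bmi_medium) == (1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            PatientProfile.from_bmi_category("obese")

    def test_state_validates_ranges(self, state):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(state, annual_moderate_rate=-0.1)
        with pytest.raises(ValueError):
            dataclasses.replace(state, alive_fraction=1.2)

    def test_equation_set_rejects_unknown_outcome(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            RiskEquationSet(equations={"blood_pressure": None})

    def test_covariate_validation_names_offender(self):
        eqs = RiskEquationSet(
            equations={"fev1": EquationSpec("fev1", coefficients={"shoe_size": 1.0})}
        )
        with pytest.raises(ValueError, match="shoe_size"):
            eqs.validate_covariates()

    def test_baseline_state_splits_exacerbation_history(self, profile):
        s = baseline_state(profile)
        assert s.annual_severe_rate == pytest.approx(0.5 * 0.20)
        assert s.annual_moderate_rate == pytest.approx(0.5 * 0.80)
        assert s.alive_fraction == 1.0
        assert s.fev1pp == profile.fev1pp0
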