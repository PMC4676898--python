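"""Synthetic inputs: reference cohort, test equation sets, traceable fixtures.

The original risk-equation coefficients were estimated from the ECLIPSE and
TORCH cohorts and are distributed as supplementary material rather than in
print, so this module provides everything needed to build and test the full
pipeline without them: the published baseline cohort table (means, standard
errors and PSA distribution families), synthetic coefficient sets whose
qualitative structure matches the disease model (FEV1 declining with age and
smoking, exacerbation rates rising as lung function falls, SGRQ worsening
with exacerbations, mortality increasing with age and falling FEV1) and
whose analytic consequences are closed-form, and a 3-cycle "known-delta"
fixture whose incremental cost and QALY outcomes can be traced by hand.

Synthetic sets claim qualitative structure only, not the magnitudes of the
original estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .econ import CostSchedule, UtilityMapping
from .engine import PSASettings, RunConfig
from .equations import (
    EquationSpec,
    PatientProfile,
    RiskEquationSet,
    baseline_state,
)
from .psa import ParameterDistribution
from .treatment import LIFETIME, TreatmentSpec


def reference_cohort() -> list[ParameterDistribution]:
    """The published baseline cohort: means, SEs and PSA families.

    Two rows in the source table lack a standard error and are stored as
    fixed: the mMRC ≥ 2 share (100% by design of the cohort) and the
    proportion of prior exacerbations that are severe (printed as 20.0 with
    a gamma family but no SE, so it cannot be sampled).  BMI medium is the
    complement of the low and high categories and has no distribution of
    its own.
    """
    P = ParameterDistribution
    return [
        P("female", "beta", 0.32, 0.0115),
        P("age", "normal", 63.3, 0.1),
        P("bmi_low", "beta", 0.104, 0.0084),
        P("bmi_high", "beta", 0.245, 0.0102),
        P("cvd_comorbidity", "beta", 0.435, 0.0113),
        P("other_comorbidity", "beta", 0.773, 0.0107),
        P("history_any_exacerbation", "beta", 0.462, 0.0121),
        P("mmrc_ge2", "fixed", 1.0, 0.0),
        P("current_smoker", "beta", 0.49, 0.0116),
        P("height", "normal", 169.0, 0.1),
        P("fibrinogen", "gamma", 458.8, 102.4),
        P("prior_exacerbations", "gamma", 0.50, 0.01),
        P("prior_severe_fraction", "fixed", 0.20, 0.0),
        P("sgrq0", "normal", 49.1, 0.5),
        P("fev1pp0", "beta", 0.477, 0.002),
        P("walk0", "normal", 378.3, 2.9),
    ]


def reference_profile() -> PatientProfile:
    """The cohort at its published means (the deterministic base case)."""
    return PatientProfile()


# --------------------------------------------------------------------------
# Synthetic equation sets with closed-form consequences
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticModelSpec:
    """Knobs for a minimal synthetic equation set with analytic behaviour.

    Every consequence is closed-form: FEV1 falls ``fev1_decline × cycle``
    mL per cycle; the exacerbation log-rate moves ``exac_log_slope_per_ml``
    per mL of FEV1 (so a fixed treatment offset gives a constant rate
    ratio); SGRQ worsens by drift plus points per exacerbation; mortality is
    an exponential hazard with an optional FEV1%p log-slope.  A zero spec
    produces identity dynamics.
    """

    fev1_decline: float = 0.0  # mL/yr
    exac_log_slope_per_ml: float = 0.0  # per mL FEV1
    base_moderate_rate: float = 0.4  # events/yr at the reference FEV1
    base_severe_rate: float = 0.1
    fev1_ref_ml: float = 1334.0
    sgrq_per_exacerbation: float = 0.0  # points per event
    sgrq_drift: float = 0.0  # points/yr
    base_mortality_hazard: float = 0.0  # per yr
    mortality_fev1pp_slope: float = 0.0  # log-hazard per FEV1%p point
    fev1pp_ref: float = 47.7
    hospitalisations_per_severe: float = 0.0
    office_visits_per_year: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fev1_decline < 0:
            raise ValueError("fev1_decline must be non-negative")
        if self.base_mortality_hazard < 0:
            raise ValueError("base_mortality_hazard must be non-negative")


def make_synthetic_equations(spec: SyntheticModelSpec) -> RiskEquationSet:
    """Build the equation set a :class:`SyntheticModelSpec` describes.

    Outcomes a zero-valued knob would leave untouched get no equation at
    all, so the all-zero spec is exactly the identity map on clinical state.
    """
    eqs: dict[str, EquationSpec | None] = {}

    if spec.fev1_decline != 0.0:
        eqs["fev1"] = EquationSpec(
            "fev1", link="identity", mode="change", intercept=-spec.fev1_decline
        )

    if spec.exac_log_slope_per_ml != 0.0:
        for outcome, base in (
            ("moderate_exac_rate", spec.base_moderate_rate),
            ("severe_exac_rate", spec.base_severe_rate),
        ):
            eqs[outcome] = EquationSpec(
                outcome,
                link="log",
                mode="direct",
                intercept=math.log(base) - spec.exac_log_slope_per_ml * spec.fev1_ref_ml,
                coefficients={"fev1_ml": spec.exac_log_slope_per_ml},
            )

    if spec.sgrq_per_exacerbation != 0.0 or spec.sgrq_drift != 0.0:
        eqs["sgrq"] = EquationSpec(
            "sgrq",
            link="identity",
            mode="change",
            intercept=spec.sgrq_drift,
            coefficients={
                "annual_moderate_rate": spec.sgrq_per_exacerbation,
                "annual_severe_rate": spec.sgrq_per_exacerbation,
            },
        )

    if spec.base_mortality_hazard > 0.0:
        coefs = {}
        intercept = math.log(spec.base_mortality_hazard)
        if spec.mortality_fev1pp_slope != 0.0:
            coefs["fev1pp"] = spec.mortality_fev1pp_slope
            intercept -= spec.mortality_fev1pp_slope * spec.fev1pp_ref
        eqs["survival"] = EquationSpec(
            "survival", link="log", mode="direct",
            intercept=intercept, coefficients=coefs,
        )

    resources: dict[str, EquationSpec | None] = {}
    if spec.hospitalisations_per_severe != 0.0:
        resources["hospitalisations"] = EquationSpec(
            "hospitalisations",
            link="identity",
            coefficients={"annual_severe_rate": spec.hospitalisations_per_severe},
        )
    if spec.office_visits_per_year != 0.0:
        resources["office_visits"] = EquationSpec(
            "office_visits", link="identity", intercept=spec.office_visits_per_year
        )

    return RiskEquationSet(equations=eqs, resource_use=resources)


def paper_like_equations() -> RiskEquationSet:
    """The package's documented default synthetic coefficient set.

    A complete linked-equation set with epidemiologically plausible
    magnitudes for a symptomatic moderate-to-severe COPD cohort: FEV1
    decline around 40 mL/year (faster for smokers, accelerating with age),
    moderate and severe exacerbation rates of about 0.30 and 0.24 per year
    at the baseline state with a log-rate slope of −0.0008 per mL FEV1,
    SGRQ worsening with exacerbations, a Gompertz-like mortality hazard
    (0.028/yr at baseline, log-slope 0.09 per year of age, −0.012 per FEV1
    percent-predicted point), and resource intensities tying hospital use to
    severe exacerbations.  Intercepts are anchored so each equation hits its
    stated baseline value at the reference cohort's starting state.
    Coefficient SEs (roughly 10–20% of each magnitude) feed second-order
    PSA sampling.
    """
    prof = reference_profile()
    s0 = baseline_state(prof)

    def anchored_intercept(target_lp: float, coefs: dict[str, float]) -> float:
        covs = prof.covariates() | s0.covariates()
        return target_lp - sum(c * covs[k] for k, c in coefs.items())

    fev1_coefs = {"current_smoker": -15.0, "age": -0.1}
    mod_coefs = {
        "fev1_ml": -0.0008,
        "prior_exacerbations": 0.5,
        "history_any_exacerbation": 0.3,
    }
    dysp_coefs = {"fev1pp": -0.05}
    cough_coefs = {"fev1pp": -0.03, "current_smoker": 0.5}
    sgrq_coefs = {"annual_moderate_rate": 0.8, "annual_severe_rate": 1.2}
    surv_coefs = {"age": 0.09, "fev1pp": -0.012, "cvd_comorbidity": 0.3}

    eqs = {
        "fev1": EquationSpec(
            "fev1", link="identity", mode="change",
            intercept=-30.0, coefficients=fev1_coefs,
            se={"intercept": 3.0, "current_smoker": 3.0, "age": 0.02},
        ),
        "moderate_exac_rate": EquationSpec(
            "moderate_exac_rate", link="log", mode="direct",
            intercept=anchored_intercept(math.log(0.30), mod_coefs),
            coefficients=mod_coefs,
            se={"intercept": 0.05, "fev1_ml": 0.0001,
                "prior_exacerbations": 0.08, "history_any_exacerbation": 0.06},
        ),
        "severe_exac_rate": EquationSpec(
            "severe_exac_rate", link="log", mode="direct",
            intercept=anchored_intercept(math.log(0.24), mod_coefs),
            coefficients=mod_coefs,
            se={"intercept": 0.05, "fev1_ml": 0.0001,
                "prior_exacerbations": 0.08, "history_any_exacerbation": 0.06},
        ),
        "dyspnoea": EquationSpec(
            "dyspnoea", link="logit", mode="direct",
            intercept=anchored_intercept(math.log(0.9 / 0.1), dysp_coefs),
            coefficients=dysp_coefs,
            se={"intercept": 0.2, "fev1pp": 0.01},
        ),
        "cough_sputum": EquationSpec(
            "cough_sputum", link="logit", mode="direct",
            intercept=anchored_intercept(math.log(0.6 / 0.4), cough_coefs),
            coefficients=cough_coefs,
            se={"intercept": 0.1, "fev1pp": 0.008, "current_smoker": 0.1},
        ),
        "walk": EquationSpec(
            "walk", link="identity", mode="change",
            intercept=-6.0, se={"intercept": 1.0},
        ),
        "sgrq": EquationSpec(
            "sgrq", link="identity", mode="change",
            intercept=0.8, coefficients=sgrq_coefs,
            se={"intercept": 0.15, "annual_moderate_rate": 0.15,
                "annual_severe_rate": 0.2},
        ),
        "survival": EquationSpec(
            "survival", link="log", mode="direct",
            intercept=anchored_intercept(math.log(0.028), surv_coefs),
            coefficients=surv_coefs,
            se={"intercept": 0.1, "age": 0.01, "fev1pp": 0.003,
                "cvd_comorbidity": 0.08},
        ),
    }

    resources = {
        "hospitalisations": EquationSpec(
            "hospitalisations", link="identity",
            coefficients={"annual_severe_rate": 1.0},
            se={"annual_severe_rate": 0.1},
        ),
        "ward_days": EquationSpec(
            "ward_days", link="identity",
            coefficients={"annual_severe_rate": 6.0},
            se={"annual_severe_rate": 0.8},
        ),
        "icu_days": EquationSpec(
            "icu_days", link="identity",
            coefficients={"annual_severe_rate": 0.2},
            se={"annual_severe_rate": 0.05},
        ),
        "er_visits": EquationSpec(
            "er_visits", link="identity",
            coefficients={"annual_moderate_rate": 0.5, "annual_severe_rate": 0.3},
            se={"annual_moderate_rate": 0.1, "annual_severe_rate": 0.08},
        ),
        "outpatient_visits": EquationSpec(
            "outpatient_visits", link="identity", intercept=2.0,
            coefficients={"annual_moderate_rate": 1.0},
            se={"intercept": 0.3, "annual_moderate_rate": 0.2},
        ),
        "office_visits": EquationSpec(
            "office_visits", link="identity", intercept=4.0,
            coefficients={"annual_moderate_rate": 2.0, "p_dyspnoea": 2.0},
            se={"intercept": 0.5, "annual_moderate_rate": 0.3, "p_dyspnoea": 0.4},
        ),
        "home_visits_day": EquationSpec(
            "home_visits_day", link="identity", intercept=0.3, se={"intercept": 0.1},
        ),
        "home_visits_night": EquationSpec(
            "home_visits_night", link="identity", intercept=0.1, se={"intercept": 0.05},
        ),
    }
    out = RiskEquationSet(equations=eqs, resource_use=resources)
    out.validate_covariates()
    return out


# --------------------------------------------------------------------------
# Treatment specifications used throughout
# --------------------------------------------------------------------------

TIOTROPIUM_PRICE_30DAY = 33.50
UMECVI_POOLED_EFFECT_ML = 92.17
UMECVI_EFFECT_CI = (61.52, 122.82)
UMECVI_EFFECT_SE = (UMECVI_EFFECT_CI[1] - UMECVI_EFFECT_CI[0]) / 3.92
INDACATEROL_PLUS_TIOTROPIUM_PRICE = 62.76


def default_treatments(
    intervention_price: float = TIOTROPIUM_PRICE_30DAY,
    effect_duration: float = LIFETIME,
) -> tuple[TreatmentSpec, TreatmentSpec]:
    """(intervention, comparator) at the published effect and prices.

    The intervention carries the pooled FEV1 benefit (92.17 mL, SE from its
    95% CI); the comparator is priced at £33.50/30 days with no shift.
    """
    intervention = TreatmentSpec(
        name="UMEC/VI",
        price_30day=intervention_price,
        effect_channel="fev1",
        effect_mean=UMECVI_POOLED_EFFECT_ML,
        effect_se=UMECVI_EFFECT_SE,
        effect_duration=effect_duration,
    )
    comparator = TreatmentSpec(name="tiotropium", price_30day=TIOTROPIUM_PRICE_30DAY)
    return intervention, comparator


def base_case_config(seed: int = 0, intervention_price: float = TIOTROPIUM_PRICE_30DAY) -> RunConfig:
    """Lifetime base case: reference cohort, default synthetic equations."""
    intervention, comparator = default_treatments(intervention_price)
    return RunConfig(
        profile=reference_profile(),
        equations=paper_like_equations(),
        intervention=intervention,
        comparator=comparator,
        horizon="lifetime",
        seed=seed,
        psa=PSASettings(cohort=tuple(reference_cohort())),
    )


# --------------------------------------------------------------------------
# The hand-traceable known-delta fixture
# --------------------------------------------------------------------------


def known_delta_fixture() -> RunConfig:
    """A 3-cycle, 1-year configuration whose ΔC and ΔQ are hand-traceable.

    One male patient, FEV1 declining 60 mL/yr, moderate exacerbation
    log-rate −0.005 per mL anchored at 0.5/yr at the baseline FEV1, no
    severe exacerbations, SGRQ worsening 1 point/yr plus 2 points per
    annual exacerbation (so the arms' utilities differ), constant mortality
    hazard 0.1/yr, one ER visit (£100) per moderate exacerbation, linear
    utility, both arms priced at £30, and a lifetime +100 mL effect on the
    intervention.  Every cycle quantity is an explicit closed form, traced
    step by step in the test suite.
    """
    profile = PatientProfile(
        female=0.0,
        age=64.0,
        height=175.0,
        prior_exacerbations=0.5,
        prior_severe_fraction=0.0,
        mmrc_ge2=1.0,
    )
    f0 = baseline_state(profile).fev1_ml
    eqs = RiskEquationSet(
        equations={
            "fev1": EquationSpec("fev1", link="identity", mode="change", intercept=-60.0),
            "moderate_exac_rate": EquationSpec(
                "moderate_exac_rate", link="log", mode="direct",
                intercept=math.log(0.5) + 0.005 * f0,
                coefficients={"fev1_ml": -0.005},
            ),
            "sgrq": EquationSpec(
                "sgrq", link="identity", mode="change", intercept=1.0,
                coefficients={"annual_moderate_rate": 2.0},
            ),
            "survival": EquationSpec(
                "survival", link="log", mode="direct", intercept=math.log(0.1)
            ),
        },
        resource_use={
            "er_visits": EquationSpec(
                "er_visits", link="identity",
                coefficients={"annual_moderate_rate": 1.0},
            ),
        },
    )
    schedule = CostSchedule(
        icu_day=0.0, ward_day=0.0, hospitalisation=0.0, er_visit=100.0,
        outpatient_visit=0.0, home_visit_day=0.0, home_visit_night=0.0,
        office_visit=0.0,
    )
    intervention = TreatmentSpec(
        name="treated", price_30day=30.0, effect_channel="fev1", effect_mean=100.0
    )
    comparator = TreatmentSpec(name="control", price_30day=30.0)
    return RunConfig(
        profile=profile,
        equations=eqs,
        intervention=intervention,
        comparator=comparator,
        schedule=schedule,
        utility=UtilityMapping.linear(),
        horizon="1y",
        discount_rate=0.035,
        seed=0,
    )


def swap_arms(config: RunConfig) -> RunConfig:
    """The same comparison with intervention and comparator exchanged."""
    return replace(
        config, intervention=config.comparator, comparator=config.intervention
    )
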