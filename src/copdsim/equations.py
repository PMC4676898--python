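"""Linked statistical risk equations driving COPD disease progression.

The disease model advances a cohort (or an individual patient) through
discrete cycles.  In each cycle the *intermediate* outcomes — FEV1,
moderate and severe exacerbation rates, dyspnoea and cough/sputum symptom
proportions, and 6-minute-walk distance — are re-predicted from the prior
cycle's state and the fixed baseline covariates; the *final* outcomes —
SGRQ health status, survival and health-care resource use — are then
predicted from the freshly updated intermediates.  Predicted outcomes at
cycle t become covariates at cycle t+1, which is what makes the equations
"linked".

Every equation is a generalized-linear-model style linear predictor with a
link function.  Level outcomes (FEV1 in mL, SGRQ points, walk metres) are
modelled as *annual increments* added to the previous level and scaled by
the cycle length; event outcomes (exacerbation rates, resource counts,
mortality hazard) and symptom proportions are predicted directly in annual
units and converted to cycle scale by the engine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

logger = logging.getLogger(__name__)

#: Valid link-function tags.  ``log`` on the survival equation means the
#: linear predictor is a log annual hazard; ``logit`` on survival means it
#: is an annual death probability.
LINKS = ("identity", "log", "logit")

#: How the link-inverse prediction enters the state: ``direct`` replaces the
#: outcome (annual units), ``change`` is an annual increment added to the
#: previous level and scaled by the cycle length.
MODES = ("direct", "change")

#: Outcomes every RiskEquationSet addresses (resource-use categories extra).
CORE_OUTCOMES = (
    "fev1",
    "moderate_exac_rate",
    "severe_exac_rate",
    "dyspnoea",
    "cough_sputum",
    "walk",
    "sgrq",
    "survival",
)

#: Health-care resource categories with per-unit NHS reference costs.
RESOURCE_CATEGORIES = (
    "icu_days",
    "ward_days",
    "hospitalisations",
    "er_visits",
    "outpatient_visits",
    "home_visits_day",
    "home_visits_night",
    "office_visits",
)


class MissingCovariateError(KeyError):
    """A coefficient names a covariate absent from the evaluation context."""


def _logistic(x: float) -> float:
    # numerically safe inverse logit
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class EquationSpec:
    """One outcome equation: intercept + coefficients, link and mode.

    ``se`` holds standard errors for second-order (parameter-uncertainty)
    sampling, keyed by covariate name with ``"intercept"`` for the
    intercept's own SE.
    """

    outcome: str
    link: str = "identity"
    mode: str = "direct"
    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)
    se: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise ValueError(
                f"equation {self.outcome!r}: unknown link {self.link!r}; "
                f"expected one of {LINKS}"
            )
        if self.mode not in MODES:
            raise ValueError(
                f"equation {self.outcome!r}: unknown mode {self.mode!r}; "
                f"expected one of {MODES}"
            )
        for name, s in self.se.items():
            if s < 0:
                raise ValueError(
                    f"equation {self.outcome!r}: negative SE for {name!r}"
                )

    def perturbed(self, draws: Mapping[str, float]) -> "EquationSpec":
        """Return a copy with intercept/coefficients shifted by ``draws``.

        ``draws`` maps covariate name (or ``"intercept"``) to an additive
        perturbation, typically SE × standard-normal, for second-order PSA.
        """
        new_int = self.intercept + draws.get("intercept", 0.0)
        new_coefs = {
            k: v + draws.get(k, 0.0) for k, v in self.coefficients.items()
        }
        return replace(self, intercept=new_int, coefficients=new_coefs)


def evaluate_equation(spec: EquationSpec, covariates: Mapping[str, float]) -> float:
    """Link-inverse of ``intercept + Σ coefficient × covariate``.

    Raises :class:`MissingCovariateError` naming the first covariate a
    coefficient references that is absent from ``covariates``.
    """
    lp = spec.intercept
    for name, coef in spec.coefficients.items():
        try:
            lp += coef * covariates[name]
        except KeyError:
            raise MissingCovariateError(
                f"equation {spec.outcome!r} needs covariate {name!r}, "
                f"not present in the evaluation context"
            ) from None
    if spec.link == "identity":
        value = lp
    elif spec.link == "log":
        value = math.exp(lp)
    elif spec.link == "logit":
        value = _logistic(lp)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown link tag {spec.link!r}")
    if not math.isfinite(value):
        raise ArithmeticError(
            f"equation {spec.outcome!r} produced non-finite value {value!r}"
        )
    return value


# --------------------------------------------------------------------------
# Patient profile and disease state
# --------------------------------------------------------------------------


def predicted_fev1_ml(female: float, age: float, height_cm: float) -> float:
    """Predicted normal FEV1 in mL (ECSC 1993 reference equations).

    ``female`` may be fractional for a cohort (mixture of the male and
    female reference equations).  Used to convert between FEV1 in mL and
    FEV1 percent-predicted.
    """
    h = height_cm / 100.0
    male_l = 4.30 * h - 0.029 * age - 2.49
    female_l = 3.95 * h - 0.025 * age - 2.60
    pred_l = (1.0 - female) * male_l + female * female_l
    return max(pred_l, 0.1) * 1000.0


@dataclass(frozen=True)
class PatientProfile:
    """Baseline covariates of the modelled cohort (or one patient).

    Proportion-valued fields hold cohort fractions in expected-value mode
    and 0/1 indicators in individual mode.  BMI is a three-level category
    with *medium* as the reference: ``bmi_low``/``bmi_high`` carry the two
    non-reference levels.
    """

    female: float = 0.32
    age: float = 63.3
    bmi_low: float = 0.104
    bmi_high: float = 0.245
    cvd_comorbidity: float = 0.435
    other_comorbidity: float = 0.773
    prior_exacerbations: float = 0.50
    prior_severe_fraction: float = 0.20
    history_any_exacerbation: float = 0.462
    mmrc_ge2: float = 1.0
    current_smoker: float = 0.49
    height: float = 169.0
    fibrinogen: float = 458.8
    sgrq0: float = 49.1
    fev1pp0: float = 47.7
    walk0: float = 378.3

    def __post_init__(self) -> None:
        for name in (
            "female", "bmi_low", "bmi_high", "cvd_comorbidity",
            "other_comorbidity", "prior_severe_fraction",
            "history_any_exacerbation", "mmrc_ge2", "current_smoker",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bmi_low + self.bmi_high > 1.0 + 1e-9:
            raise ValueError("bmi_low + bmi_high exceeds 1")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not 0.0 <= self.sgrq0 <= 100.0:
            raise ValueError("sgrq0 must be in [0, 100]")
        if not 0.0 < self.fev1pp0 <= 150.0:
            raise ValueError("fev1pp0 must be in (0, 150]")
        if self.walk0 < 0:
            raise ValueError("walk0 must be non-negative")
        if self.prior_exacerbations < 0:
            raise ValueError("prior_exacerbations must be non-negative")

    @classmethod
    def from_bmi_category(cls, bmi_category: str, **kwargs) -> "PatientProfile":
        """Build an individual profile from a categorical BMI level."""
        if bmi_category not in ("low", "medium", "high"):
            raise ValueError(f"unknown bmi_category {bmi_category!r}")
        return cls(
            bmi_low=1.0 if bmi_category == "low" else 0.0,
            bmi_high=1.0 if bmi_category == "high" else 0.0,
            **kwargs,
        )

    @property
    def bmi_medium(self) -> float:
        return 1.0 - self.bmi_low - self.bmi_high

    @property
    def predicted_fev1_ml(self) -> float:
        """Predicted normal FEV1 (mL), frozen at the baseline age."""
        return predicted_fev1_ml(self.female, self.age, self.height)

    def covariates(self) -> dict[str, float]:
        """Baseline covariates by name, for equation evaluation."""
        return {f.name: getattr(self, f.name) for f in fields(self)} | {
            "bmi_medium": self.bmi_medium,
            "male": 1.0 - self.female,
        }


@dataclass(frozen=True)
class DiseaseState:
    """Time-varying clinical state of the cohort at the end of a cycle.

    Event rates are annual; the engine rescales them to cycle length.
    ``alive_fraction`` is the cohort-survival interpretation of mortality.
    """

    fev1_ml: float
    fev1pp: float
    sgrq: float
    p_dyspnoea: float
    p_cough_sputum: float
    walk_m: float
    annual_moderate_rate: float
    annual_severe_rate: float
    alive_fraction: float
    age: float

    def __post_init__(self) -> None:
        if self.annual_moderate_rate < 0 or self.annual_severe_rate < 0:
            raise ValueError("annual exacerbation rates must be non-negative")
        for name in ("p_dyspnoea", "p_cough_sputum", "alive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.sgrq <= 100.0:
            raise ValueError("sgrq must be in [0, 100]")

    def covariates(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def baseline_state(
    profile: PatientProfile, p_cough_sputum: float = 0.6
) -> DiseaseState:
    """Initial disease state at model entry (t = 0).

    The prior-year exacerbation history is split into moderate and severe
    annual rates by the severe fraction; the dyspnoea proportion starts at
    the mMRC ≥ 2 share (the symptom the scale measures); baseline cough and
    sputum prevalence is not part of the baseline table and defaults to a
    typical symptomatic-cohort value unless supplied.
    """
    sev = profile.prior_exacerbations * profile.prior_severe_fraction
    mod = profile.prior_exacerbations - sev
    return DiseaseState(
        fev1_ml=profile.fev1pp0 / 100.0 * profile.predicted_fev1_ml,
        fev1pp=profile.fev1pp0,
        sgrq=profile.sgrq0,
        p_dyspnoea=profile.mmrc_ge2,
        p_cough_sputum=p_cough_sputum,
        walk_m=profile.walk0,
        annual_moderate_rate=mod,
        annual_severe_rate=sev,
        alive_fraction=1.0,
        age=profile.age,
    )


# --------------------------------------------------------------------------
# Equation sets
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskEquationSet:
    """Coefficient sets for the linked outcome equations.

    An outcome mapped to ``None`` has no equation and carries forward
    unchanged (rates and levels alike), which makes the all-``None`` set
    the identity map on clinical fields.
    """

    equations: Mapping[str, EquationSpec | None]
    resource_use: Mapping[str, EquationSpec | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for out in self.equations:
            if out not in CORE_OUTCOMES:
                raise ValueError(
                    f"unknown outcome {out!r}; expected one of {CORE_OUTCOMES}"
                )
        for cat in self.resource_use:
            if cat not in RESOURCE_CATEGORIES:
                raise ValueError(
                    f"unknown resource category {cat!r}; "
                    f"expected one of {RESOURCE_CATEGORIES}"
                )

    def __getitem__(self, outcome: str) -> EquationSpec | None:
        return self.equations.get(outcome)

    @classmethod
    def null(cls) -> "RiskEquationSet":
        """Identity dynamics: no equations, state carried forward."""
        return cls(equations={}, resource_use={})

    def validate_covariates(self) -> None:
        """Check every referenced covariate resolves to a known field."""
        known = set(PatientProfile().covariates()) | {
            f.name for f in fields(DiseaseState)
        }
        for spec in list(self.equations.values()) + list(self.resource_use.values()):
            if spec is None:
                continue
            for name in spec.coefficients:
                if name not in known:
                    raise ValueError(
                        f"equation {spec.outcome!r}: covariate {name!r} does "
                        f"not resolve to a PatientProfile or DiseaseState field"
                    )

    def all_specs(self) -> list[EquationSpec]:
        return [
            s
            for s in list(self.equations.values()) + list(self.resource_use.values())
            if s is not None
        ]

    def perturbed(
        self, draws: Mapping[str, Mapping[str, float]]
    ) -> "RiskEquationSet":
        """Equation set with coefficients shifted per-outcome (second-order PSA)."""
        eqs = {
            out: (spec.perturbed(draws.get(out, {})) if spec is not None else None)
            for out, spec in self.equations.items()
        }
        res = {
            cat: (
                spec.perturbed(draws.get(f"resource_use.{cat}", {}))
                if spec is not None
                else None
            )
            for cat, spec in self.resource_use.items()
        }
        return RiskEquationSet(equations=eqs, resource_use=res)


def _clamp(value: float, lo: float, hi: float, what: str) -> float:
    if value < lo or value > hi:
        logger.warning("predicted %s = %.4g outside [%g, %g]; clamped", what, value, lo, hi)
        return min(max(value, lo), hi)
    return value


def _predict(
    spec: EquationSpec | None,
    prev: float,
    covs: Mapping[str, float],
    cycle_years: float,
) -> float:
    """Apply one equation: absent → carry forward; change-mode scales by cycle."""
    if spec is None:
        return prev
    value = evaluate_equation(spec, covs)
    if spec.mode == "change":
        return prev + cycle_years * value
    return value


def advance_state(
    state: DiseaseState,
    profile: PatientProfile,
    eqs: RiskEquationSet,
    cycle_years: float,
) -> DiseaseState:
    """Advance the disease state one cycle through the linked equations.

    Stage 1 predicts the intermediate outcomes from the prior state; stage 2
    predicts SGRQ from the updated intermediates.  Event rates stay in
    annual units (the engine rescales); predictions are clamped to their
    valid ranges with a logged warning.  Survival is *not* applied here —
    :func:`cycle_survival` returns the cycle's survivor fraction and the
    engine multiplies it into ``alive_fraction``.
    """
    if cycle_years <= 0:
        raise ValueError("cycle_years must be positive")

    cov1 = profile.covariates() | state.covariates()

    fev1_ml = max(_predict(eqs["fev1"], state.fev1_ml, cov1, cycle_years), 0.0)
    mod = max(
        _predict(eqs["moderate_exac_rate"], state.annual_moderate_rate, cov1, cycle_years),
        0.0,
    )
    sev = max(
        _predict(eqs["severe_exac_rate"], state.annual_severe_rate, cov1, cycle_years),
        0.0,
    )
    dysp = _clamp(
        _predict(eqs["dyspnoea"], state.p_dyspnoea, cov1, cycle_years),
        0.0, 1.0, "p_dyspnoea",
    )
    cough = _clamp(
        _predict(eqs["cough_sputum"], state.p_cough_sputum, cov1, cycle_years),
        0.0, 1.0, "p_cough_sputum",
    )
    walk = max(_predict(eqs["walk"], state.walk_m, cov1, cycle_years), 0.0)

    if eqs["fev1"] is None:  # keep the identity map exact
        fev1pp = state.fev1pp
    else:
        fev1pp = fev1_ml / profile.predicted_fev1_ml * 100.0

    # stage 2: final outcomes see the freshly updated intermediates
    cov2 = cov1 | {
        "fev1_ml": fev1_ml,
        "fev1pp": fev1pp,
        "annual_moderate_rate": mod,
        "annual_severe_rate": sev,
        "p_dyspnoea": dysp,
        "p_cough_sputum": cough,
        "walk_m": walk,
        "age": state.age + cycle_years,
    }
    sgrq = _clamp(
        _predict(eqs["sgrq"], state.sgrq, cov2, cycle_years), 0.0, 100.0, "sgrq"
    )

    return DiseaseState(
        fev1_ml=fev1_ml,
        fev1pp=fev1pp,
        sgrq=sgrq,
        p_dyspnoea=dysp,
        p_cough_sputum=cough,
        walk_m=walk,
        annual_moderate_rate=mod,
        annual_severe_rate=sev,
        alive_fraction=state.alive_fraction,
        age=state.age + cycle_years,
    )


def annual_to_cycle(value: float, cycle_years: float, kind: str) -> float:
    """Rescale an annual rate or probability to a cycle of given length.

    Rates scale linearly; probabilities convert through the survival
    product, ``1 − (1 − p)**cycle_years``, so that subdividing a year and
    composing the pieces reproduces the annual probability exactly.
    """
    if cycle_years <= 0:
        raise ValueError("cycle_years must be positive")
    if kind == "rate":
        return value * cycle_years
    if kind == "probability":
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"probability must be in [0, 1], got {value}")
        return 1.0 - (1.0 - value) ** cycle_years
    raise ValueError(f"unknown kind {kind!r}; expected 'rate' or 'probability'")


def cycle_survival(
    state: DiseaseState,
    profile: PatientProfile,
    eqs: RiskEquationSet,
    cycle_years: float,
) -> float:
    """Fraction of the cohort surviving one cycle, in [0, 1].

    The survival equation's link decides the hazard form: ``log`` means the
    linear predictor is a log annual hazard (exponential survival within the
    cycle, the default), ``identity`` an annual hazard directly, and
    ``logit`` an annual death probability converted through
    :func:`annual_to_cycle`.  No equation means no mortality.
    """
    if not 0.0 < state.alive_fraction <= 1.0:
        raise ValueError("alive_fraction must be in (0, 1]")
    spec = eqs["survival"]
    if spec is None:
        return 1.0
    covs = profile.covariates() | state.covariates()
    value = evaluate_equation(spec, covs)
    if spec.link == "logit":
        p_death = annual_to_cycle(value, cycle_years, "probability")
        return 1.0 - p_death
    hazard = max(value, 0.0)
    return math.exp(-hazard * cycle_years)


def resource_use(
    state: DiseaseState,
    profile: PatientProfile,
    eqs: RiskEquationSet,
    cycle_years: float,
) -> dict[str, float]:
    """Expected per-person resource counts for one cycle, by category.

    Each resource equation predicts an annual count; counts scale linearly
    with the cycle length and negative predictions clamp to zero with a
    logged warning.  Categories without an equation contribute zero.
    """
    covs = profile.covariates() | state.covariates()
    counts: dict[str, float] = {}
    for cat in RESOURCE_CATEGORIES:
        spec = eqs.resource_use.get(cat)
        if spec is None:
            counts[cat] = 0.0
            continue
        annual = evaluate_equation(spec, covs)
        if annual < 0:
            logger.warning("predicted %s = %.4g < 0; clamped to 0", cat, annual)
            annual = 0.0
        counts[cat] = annual * cycle_years
    return counts
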