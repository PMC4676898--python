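"""Probabilistic sensitivity analysis and acceptability curves.

Two layers of uncertainty are propagated: *first order* resamples the
baseline cohort parameters from their published distributions (beta for
proportions, normal for symmetric continuous measures, gamma for skewed
positive ones, matched to the stated mean and standard error by the method
of moments); *second order* perturbs every risk-equation coefficient and the
pooled treatment effect by independent normals on their standard errors.
Each replicate reruns both arms and records (ΔC, ΔQ); the cost-effectiveness
acceptability curve is the fraction of replicates with positive net monetary
benefit across a willingness-to-pay grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .econ import net_monetary_benefit
from .engine import RunConfig, run_comparison
from .equations import PatientProfile, RiskEquationSet

logger = logging.getLogger(__name__)

FAMILIES = ("beta", "normal", "gamma", "fixed")


@dataclass(frozen=True)
class ParameterDistribution:
    """A baseline parameter's sampling distribution (mean + SE family)."""

    name: str
    family: str
    mean: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"parameter {self.name!r}: unknown family {self.family!r}"
            )
        if self.se < 0:
            raise ValueError(f"parameter {self.name!r}: se must be non-negative")
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ValueError(f"parameter {self.name!r}: beta mean must be in (0,1)")
        if self.family == "gamma" and self.mean <= 0:
            raise ValueError(f"parameter {self.name!r}: gamma mean must be positive")


def sample_parameter(dist: ParameterDistribution, rng: np.random.Generator) -> float:
    """One draw from a parameter's distribution, moment-matched to (mean, se).

    Beta: α = m(m(1−m)/se² − 1), β = α(1−m)/m.  Gamma: shape = m²/se²,
    scale = se²/m.  An SE of zero collapses any family to the mean.
    """
    m, s = dist.mean, dist.se
    if dist.family == "fixed" or s == 0.0:
        return m
    if dist.family == "normal":
        return float(rng.normal(m, s))
    if dist.family == "gamma":
        shape = m * m / (s * s)
        scale = s * s / m
        return float(rng.gamma(shape, scale))
    # beta
    if s * s >= m * (1.0 - m):
        raise ValueError(
            f"parameter {dist.name!r}: beta moment matching infeasible "
            f"(se^2 = {s*s:.4g} >= mean(1-mean) = {m*(1-m):.4g})"
        )
    alpha = m * (m * (1.0 - m) / (s * s) - 1.0)
    beta = alpha * (1.0 - m) / m
    return float(rng.beta(alpha, beta))


def beta_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (α, β) for a beta distribution."""
    if se * se >= mean * (1.0 - mean):
        raise ValueError("beta moment matching infeasible")
    alpha = mean * (mean * (1.0 - mean) / (se * se) - 1.0)
    return alpha, alpha * (1.0 - mean) / mean


def gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) for a gamma distribution."""
    return mean * mean / (se * se), se * se / mean


#: Profile fields sampled on the percent scale from a proportion-scale beta.
_PERCENT_SCALED = {"fev1pp0"}
#: Proportion-valued profile fields that must stay in [0, 1] after sampling.
_PROPORTIONS = {
    "female", "bmi_low", "bmi_high", "cvd_comorbidity", "other_comorbidity",
    "prior_severe_fraction", "history_any_exacerbation", "mmrc_ge2",
    "current_smoker",
}


def draw_profile(
    table: Sequence[ParameterDistribution], rng: np.random.Generator
) -> PatientProfile:
    """Sample one internally consistent baseline profile.

    BMI low/high draws are renormalised if they exceed 1 together (medium is
    the complement); proportions are clamped to [0, 1]; FEV1 percent
    predicted is sampled as a proportion and rescaled to percent.
    """
    values: dict[str, float] = {}
    for dist in table:
        v = sample_parameter(dist, rng)
        if dist.name in _PERCENT_SCALED:
            v *= 100.0
        elif dist.name in _PROPORTIONS:
            v = min(max(v, 0.0), 1.0)
        values[dist.name] = v

    missing = [
        f for f in (
            "female", "age", "bmi_low", "bmi_high", "cvd_comorbidity",
            "other_comorbidity", "prior_exacerbations", "prior_severe_fraction",
            "history_any_exacerbation", "mmrc_ge2", "current_smoker", "height",
            "fibrinogen", "sgrq0", "fev1pp0", "walk0",
        ) if f not in values
    ]
    if missing:
        raise ValueError(f"cohort parameter set is missing: {missing}")

    s = values["bmi_low"] + values["bmi_high"]
    if s > 1.0:
        values["bmi_low"] /= s
        values["bmi_high"] /= s
    values["sgrq0"] = min(max(values["sgrq0"], 0.0), 100.0)
    values["fev1pp0"] = min(max(values["fev1pp0"], 1e-6), 150.0)
    values["walk0"] = max(values["walk0"], 0.0)
    values["prior_exacerbations"] = max(values["prior_exacerbations"], 0.0)
    values["fibrinogen"] = max(values["fibrinogen"], 0.0)
    return PatientProfile(**values)


#: Indicator fields binarised in individual-level (one patient) PSA mode.
_BERNOULLI_FIELDS = (
    "female", "cvd_comorbidity", "other_comorbidity",
    "history_any_exacerbation", "mmrc_ge2", "current_smoker",
)


def individualize_profile(
    profile: PatientProfile, rng: np.random.Generator
) -> PatientProfile:
    """Turn a cohort-mean profile into one sampled patient.

    Proportion-valued fields become Bernoulli indicators and the BMI
    category is a single multinomial draw; continuous fields keep their
    sampled values.  Used by the PSA's ``individual`` first-order mode.
    """
    values = {f: float(rng.random() < getattr(profile, f)) for f in _BERNOULLI_FIELDS}
    u = rng.random()
    low, high = profile.bmi_low, profile.bmi_high
    values["bmi_low"] = float(u < low)
    values["bmi_high"] = float(u >= 1.0 - high)
    return replace(profile, **values)


def _sample_equations(
    eqs: RiskEquationSet, rng: np.random.Generator
) -> tuple[RiskEquationSet, dict[str, dict[str, float]]]:
    """Second-order draw: independent normal perturbations per coefficient SE."""
    draws: dict[str, dict[str, float]] = {}
    for key, spec in list(eqs.equations.items()) + [
        (f"resource_use.{c}", s) for c, s in eqs.resource_use.items()
    ]:
        if spec is None or not spec.se:
            continue
        draws[key] = {
            name: float(rng.normal(0.0, s)) for name, s in spec.se.items() if s > 0
        }
    return eqs.perturbed(draws), draws


@dataclass(frozen=True)
class PSADraw:
    """One probabilistic replicate's inputs and incremental outcomes."""

    replicate: int
    profile: PatientProfile
    coefficient_draws: dict[str, dict[str, float]]
    treatment_effect: float
    delta_cost: float
    delta_qaly: float
    delta_ly: float


def run_psa(
    config: RunConfig,
    n_iterations: int | None = None,
    seed: int | None = None,
) -> tuple[list[PSADraw], int]:
    """Run the probabilistic sensitivity analysis.

    Returns the list of successful replicates and the count of excluded
    (failed) ones.  Each replicate uses its own child stream of the seed, so
    results are independent of execution order and reproducible.
    """
    n = n_iterations if n_iterations is not None else config.psa.n_iterations
    if n < 1:
        raise ValueError("n_iterations must be at least 1")
    seed = config.seed if seed is None else seed

    cohort = config.psa.cohort
    if cohort is None:
        from .synthetic import reference_cohort

        cohort = reference_cohort()

    streams = np.random.SeedSequence(seed).spawn(n)
    draws: list[PSADraw] = []
    excluded = 0
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        try:
            profile = draw_profile(cohort, rng)
            if config.psa.mode == "individual":
                profile = individualize_profile(profile, rng)
            eqs, coef_draws = _sample_equations(config.equations, rng)
            effect = config.intervention.effect_mean
            if config.intervention.effect_se > 0:
                effect = float(rng.normal(effect, config.intervention.effect_se))
                if config.psa.truncate_effect_at_zero:
                    effect = max(effect, 0.0)
            rep_config = replace(
                config,
                profile=profile,
                equations=eqs,
                intervention=replace(config.intervention, effect_mean=effect),
            )
            comparison, _ = run_comparison(rep_config)
            if not (
                math.isfinite(comparison.delta_cost)
                and math.isfinite(comparison.delta_qaly)
            ):
                raise ArithmeticError("non-finite incremental outcome")
            draws.append(
                PSADraw(
                    replicate=rep,
                    profile=profile,
                    coefficient_draws=coef_draws,
                    treatment_effect=effect,
                    delta_cost=comparison.delta_cost,
                    delta_qaly=comparison.delta_qaly,
                    delta_ly=comparison.delta_ly,
                )
            )
        except Exception as exc:  # noqa: BLE001 - tail draws must not kill a run
            excluded += 1
            logger.warning("replicate %d excluded: %s", rep, exc)
    if excluded:
        logger.info("PSA excluded %d of %d replicates", excluded, n)
    return draws, excluded


def draws_to_frame(draws: Sequence[PSADraw]) -> pd.DataFrame:
    """Tabulate replicates as (replicate, delta_cost, delta_qaly, delta_ly)."""
    return pd.DataFrame(
        {
            "replicate": [d.replicate for d in draws],
            "delta_cost": [d.delta_cost for d in draws],
            "delta_qaly": [d.delta_qaly for d in draws],
            "delta_ly": [d.delta_ly for d in draws],
        }
    )


@dataclass(frozen=True)
class CEACCurve:
    """Cost-effectiveness acceptability curve over willingness-to-pay."""

    points: tuple[tuple[float, float], ...]

    def probability_at(self, wtp: float) -> float:
        for w, p in self.points:
            if w == wtp:
                return p
        raise KeyError(f"wtp {wtp} not on the curve grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["wtp", "probability"])


def ceac(draws: Sequence[PSADraw], wtp_grid: Sequence[float]) -> CEACCurve:
    """Probability of positive net monetary benefit at each willingness-to-pay."""
    if len(draws) == 0:
        raise ValueError("ceac requires at least one draw")
    dc = np.array([d.delta_cost for d in draws])
    dq = np.array([d.delta_qaly for d in draws])
    points = []
    for wtp in wtp_grid:
        nmb = wtp * dq - dc
        points.append((float(wtp), float(np.mean(nmb > 0))))
    return CEACCurve(points=tuple(points))


def probability_cost_effective(draws: Sequence[PSADraw], wtp: float) -> float:
    """Fraction of replicates with positive net monetary benefit at one threshold."""
    return float(
        np.mean([net_monetary_benefit(d.delta_cost, d.delta_qaly, wtp) > 0 for d in draws])
    )
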