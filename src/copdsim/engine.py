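"""Simulation engine: cycle plans, per-arm propagation, scenario runs.

A run advances the cohort through a cycle plan — two 3-month "trial period"
cycles followed by 6-month cycles to the horizon — applying the treatment
effect, re-predicting the disease state through the linked equations,
and accumulating survival-weighted, discounted costs, QALYs and life-years
plus undiscounted exacerbation counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .econ import (
    CEComparison,
    CostSchedule,
    UtilityMapping,
    compare_arms,
    cycle_cost,
    discount_factor,
    sgrq_to_eq5d,
)
from .equations import (
    DiseaseState,
    PatientProfile,
    RiskEquationSet,
    advance_state,
    annual_to_cycle,
    baseline_state,
    cycle_survival,
    resource_use,
)
from .treatment import TreatmentSpec, apply_effect, effect_at_time

logger = logging.getLogger(__name__)

HORIZONS = ("1y", "5y", "lifetime")
ACCRUALS = ("half_cycle", "start_of_cycle")
TRIAL_CYCLES = (0.25, 0.25)  # the 6-month trial period, as two 3-month cycles
EXTINCTION = 1e-12


@dataclass(frozen=True)
class CyclePlan:
    """Ordered cycle lengths (years) making up the model time frame."""

    lengths: tuple[float, ...]
    horizon: str
    age_cap: float | None = None

    @property
    def total_years(self) -> float:
        return sum(self.lengths)

    def midpoints(self) -> list[float]:
        out, t = [], 0.0
        for length in self.lengths:
            out.append(t + length / 2.0)
            t += length
        return out


def build_cycle_plan(
    horizon: str, start_age: float = 63.3, age_cap: float = 100.0
) -> CyclePlan:
    """Cycle plan for a horizon tag: two 0.25-y cycles then 0.5-y cycles.

    ``lifetime`` runs to the age cap, truncating the final cycle; ``1y`` and
    ``5y`` are the short-horizon scenarios.
    """
    if horizon not in HORIZONS:
        raise ValueError(f"unknown horizon {horizon!r}; expected one of {HORIZONS}")
    if start_age >= age_cap:
        raise ValueError("start_age must be below age_cap")
    if horizon == "1y":
        total = 1.0
    elif horizon == "5y":
        total = 5.0
    else:
        total = age_cap - start_age
    remaining = total - sum(TRIAL_CYCLES)
    if remaining < 0:
        raise ValueError("horizon shorter than the 6-month trial period")
    n_full = int(math.floor(remaining / 0.5 + 1e-9))
    lengths = list(TRIAL_CYCLES) + [0.5] * n_full
    leftover = remaining - 0.5 * n_full
    if leftover > 1e-9:
        lengths.append(round(leftover, 12))
    return CyclePlan(
        lengths=tuple(lengths),
        horizon=horizon,
        age_cap=age_cap if horizon == "lifetime" else None,
    )


@dataclass(frozen=True)
class CycleOutcome:
    """Per-cycle accounting record (survival-weighted, costs discounted)."""

    cycle: int
    t_start: float
    length: float
    alive_start: float
    alive_end: float
    moderate_events: float
    severe_events: float
    resource_cost: float
    drug_cost: float
    qalys: float
    life_years: float
    utility: float


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals and the trajectory for one treatment arm."""

    name: str
    costs: dict[str, float]  # discounted GBP by category, incl. "drug"
    qalys: float
    life_years: float  # undiscounted
    life_years_discounted: float
    moderate_exacs: float  # undiscounted expected counts
    severe_exacs: float
    trajectory: tuple[CycleOutcome, ...]
    states: tuple[DiseaseState, ...]

    @property
    def total_cost(self) -> float:
        return sum(self.costs.values())

    @property
    def resource_cost(self) -> float:
        return sum(v for k, v in self.costs.items() if k != "drug")


def run_arm(
    profile: PatientProfile,
    treatment: TreatmentSpec,
    eqs: RiskEquationSet,
    schedule: CostSchedule,
    plan: CyclePlan,
    discount_rate: float = 0.035,
    utility: UtilityMapping | None = None,
    accrual: str = "half_cycle",
    p_cough_sputum0: float = 0.6,
) -> ArmResult:
    """Propagate one arm through the cycle plan and accumulate outcomes.

    Each cycle: bring the treatment's FEV1 (or SGRQ) shift to the level in
    force at the cycle start, advance the linked equations, convert annual
    rates to the cycle scale, and accrue survival-weighted flows discounted
    at the cycle midpoint.  The accrual weight is the alive fraction at the
    cycle start times the square root of the cycle's survivor fraction
    (survival to the midpoint) under ``half_cycle`` accrual, or the starting
    alive fraction alone under ``start_of_cycle``.
    """
    if accrual not in ACCRUALS:
        raise ValueError(f"unknown accrual {accrual!r}; expected one of {ACCRUALS}")
    utility = utility or UtilityMapping()
    male = 1.0 - profile.female

    state = baseline_state(profile, p_cough_sputum=p_cough_sputum0)
    applied_offset = 0.0
    costs: dict[str, float] = {"drug": 0.0}
    qalys = ly = lyd = mod_total = sev_total = 0.0
    trajectory: list[CycleOutcome] = []
    states: list[DiseaseState] = [state]

    t = 0.0
    for i, length in enumerate(plan.lengths):
        alive_start = state.alive_fraction
        if alive_start < EXTINCTION:
            logger.info("cohort extinct at cycle %d (t=%.2f); truncating", i, t)
            break

        # bring the treatment shift to the level in force at this cycle start
        target = effect_at_time(treatment, t)
        delta = target - applied_offset
        if delta != 0.0:
            shim = replace(treatment, effect_mean=delta, effect_duration=float("inf"))
            state = apply_effect(state, shim, 0.0)
            applied_offset = target

        new_state = advance_state(state, profile, eqs, length)
        surv = cycle_survival(new_state, profile, eqs, length)
        if accrual == "half_cycle":
            w = alive_start * math.sqrt(surv)
        else:
            w = alive_start

        t_mid = t + length / 2.0
        df = discount_factor(t_mid, discount_rate)

        mod_ev = w * annual_to_cycle(new_state.annual_moderate_rate, length, "rate")
        sev_ev = w * annual_to_cycle(new_state.annual_severe_rate, length, "rate")
        mod_total += mod_ev
        sev_total += sev_ev

        counts = resource_use(new_state, profile, eqs, length)
        cc = cycle_cost(counts, schedule, treatment.price_30day, length)
        for cat, cost in cc.resource.items():
            costs[cat] = costs.get(cat, 0.0) + w * cost * df
        costs["drug"] += w * cc.drug * df

        u = sgrq_to_eq5d(new_state.sgrq, utility, male=male)
        qalys += w * length * u * df
        ly += w * length
        lyd += w * length * df

        alive_end = alive_start * surv
        state = replace(new_state, alive_fraction=alive_end)
        states.append(state)
        trajectory.append(
            CycleOutcome(
                cycle=i,
                t_start=t,
                length=length,
                alive_start=alive_start,
                alive_end=alive_end,
                moderate_events=mod_ev,
                severe_events=sev_ev,
                resource_cost=w * cc.resource_total * df,
                drug_cost=w * cc.drug * df,
                qalys=w * length * u * df,
                life_years=w * length,
                utility=u,
            )
        )
        t += length

    return ArmResult(
        name=treatment.name,
        costs=costs,
        qalys=qalys,
        life_years=ly,
        life_years_discounted=lyd,
        moderate_exacs=mod_total,
        severe_exacs=sev_total,
        trajectory=tuple(trajectory),
        states=tuple(states),
    )


# --------------------------------------------------------------------------
# Run configuration and scenario orchestration
# --------------------------------------------------------------------------

SCENARIOS = ("base", "A", "B", "C")


@dataclass(frozen=True)
class PSASettings:
    """Probabilistic-sensitivity-analysis block of a run configuration."""

    n_iterations: int = 5000
    wtp_max: float = 50_000.0
    wtp_step: float = 1_000.0
    mode: str = "cohort"  # "cohort": one mean-parameter draw per replicate;
    # "individual": one sampled patient per replicate
    cohort: tuple | None = None  # ParameterDistribution list; None = reference
    truncate_effect_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("cohort", "individual"):
            raise ValueError(f"unknown PSA mode {self.mode!r}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")

    def wtp_grid(self) -> list[float]:
        n = int(self.wtp_max // self.wtp_step)
        return [i * self.wtp_step for i in range(n + 1)]


@dataclass(frozen=True)
class RunConfig:
    """Everything one comparison run needs, reproducibly."""

    profile: PatientProfile
    equations: RiskEquationSet
    intervention: TreatmentSpec
    comparator: TreatmentSpec
    schedule: CostSchedule = field(default_factory=CostSchedule)
    utility: UtilityMapping = field(default_factory=UtilityMapping)
    horizon: str = "lifetime"
    discount_rate: float = 0.035
    age_cap: float = 100.0
    seed: int = 0
    accrual: str = "half_cycle"
    p_cough_sputum0: float = 0.6
    psa: PSASettings = field(default_factory=PSASettings)

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")
        if self.horizon not in HORIZONS:
            raise ValueError(f"unknown horizon {self.horizon!r}")
        if self.accrual not in ACCRUALS:
            raise ValueError(f"unknown accrual {self.accrual!r}")

    def plan(self) -> CyclePlan:
        return build_cycle_plan(self.horizon, self.profile.age, self.age_cap)


def run_comparison(config: RunConfig) -> tuple[CEComparison, dict[str, ArmResult]]:
    """Run both arms under identical settings and compare them."""
    plan = config.plan()
    arms = {}
    for key, treatment in (
        ("intervention", config.intervention),
        ("comparator", config.comparator),
    ):
        arms[key] = run_arm(
            config.profile,
            treatment,
            config.equations,
            config.schedule,
            plan,
            discount_rate=config.discount_rate,
            utility=config.utility,
            accrual=config.accrual,
            p_cough_sputum0=config.p_cough_sputum0,
        )
    comparison = compare_arms(arms["intervention"], arms["comparator"])
    return comparison, arms


def scenario_config(which: str, config: RunConfig) -> RunConfig:
    """Derive a scenario's configuration from the base configuration.

    ``base`` = lifetime horizon with the configured (lifetime) effect
    duration; ``A`` = 1-year horizon; ``B`` = 5-year horizon; ``C`` =
    lifetime horizon with a 12-month treatment-effect duration.
    """
    if which not in SCENARIOS:
        raise ValueError(f"unknown scenario {which!r}; expected one of {SCENARIOS}")
    if which == "base":
        return replace(config, horizon="lifetime")
    if which == "A":
        return replace(config, horizon="1y")
    if which == "B":
        return replace(config, horizon="5y")
    return replace(
        config,
        horizon="lifetime",
        intervention=replace(config.intervention, effect_duration=1.0),
    )


def run_scenario(
    which: str, config: RunConfig
) -> tuple[CEComparison, dict[str, ArmResult]]:
    """Run one of the named scenarios off the base configuration."""
    return run_comparison(scenario_config(which, config))
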