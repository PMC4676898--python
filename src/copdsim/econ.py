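"""Costs, utilities and incremental cost-effectiveness.

Clinical trajectories become economic outcomes through four pieces: a
SGRQ → EQ-5D utility mapping, a unit-cost schedule applied to resource
counts plus a 30-day drug price, continuous-time discounting at 3.5%/year,
and the incremental comparison (ΔC, ΔQ, ICER or a dominance verdict, net
monetary benefit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

from .equations import RESOURCE_CATEGORIES

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CostSchedule:
    """Per-unit health-care costs (GBP).  Defaults are NHS reference costs."""

    icu_day: float = 1190.29
    ward_day: float = 514.00
    hospitalisation: float = 1897.00
    er_visit: float = 123.74
    outpatient_visit: float = 150.00
    home_visit_day: float = 114.00
    home_visit_night: float = 114.00
    office_visit: float = 67.00
    currency_year: str = "2011-2012"  # metadata only; no inflation adjustment

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.type == "float" and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def unit_cost(self, category: str) -> float:
        return {
            "icu_days": self.icu_day,
            "ward_days": self.ward_day,
            "hospitalisations": self.hospitalisation,
            "er_visits": self.er_visit,
            "outpatient_visits": self.outpatient_visit,
            "home_visits_day": self.home_visit_day,
            "home_visits_night": self.home_visit_night,
            "office_visits": self.office_visit,
        }[category]


@dataclass(frozen=True)
class UtilityMapping:
    """Maps SGRQ total score (0 best – 100 worst) to EQ-5D utility.

    ``form`` is ``"quadratic"`` (the published response-mapping shape,
    default) or ``"linear"``.  Coefficients are on (intercept, sgrq, sgrq²,
    male); utilities are clamped to [floor, 1].
    """

    form: str = "quadratic"
    intercept: float = 0.9617
    sgrq_coef: float = -0.0013
    sgrq2_coef: float = -0.0001
    male_coef: float = 0.0231
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("quadratic", "linear"):
            raise ValueError(f"unknown utility mapping form {self.form!r}")

    @classmethod
    def linear(cls) -> "UtilityMapping":
        """Simple test mapping u = 1 − SGRQ/100."""
        return cls(form="linear", intercept=1.0, sgrq_coef=-0.01,
                   sgrq2_coef=0.0, male_coef=0.0)

    @classmethod
    def flat(cls, value: float = 1.0) -> "UtilityMapping":
        """Constant utility, useful for life-year-only checks."""
        return cls(form="linear", intercept=value, sgrq_coef=0.0,
                   sgrq2_coef=0.0, male_coef=0.0)


def sgrq_to_eq5d(sgrq: float, mapping: UtilityMapping, male: float = 0.0) -> float:
    """EQ-5D utility for an SGRQ score under a mapping.

    ``male`` is the male fraction (cohort) or indicator (individual); it is
    ignored by mappings with a zero male coefficient.
    """
    if not 0.0 <= sgrq <= 100.0:
        raise ValueError(f"sgrq must be in [0, 100], got {sgrq}")
    u = mapping.intercept + mapping.sgrq_coef * sgrq + mapping.male_coef * male
    if mapping.form == "quadratic":
        u += mapping.sgrq2_coef * sgrq**2
    return min(max(u, mapping.floor), 1.0)


def discount_factor(time: float, annual_rate: float) -> float:
    """Continuous-time discount factor (1 + rate)^(−time).

    The continuous exponent makes 3-month and 6-month cycles discount
    consistently with annual accounting.
    """
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    if time < 0:
        raise ValueError("time must be non-negative")
    return (1.0 + annual_rate) ** (-time)


@dataclass(frozen=True)
class CycleCost:
    """Cost breakdown for one cycle (per cohort member, undiscounted)."""

    resource: dict[str, float]
    drug: float

    @property
    def resource_total(self) -> float:
        return sum(self.resource.values())

    @property
    def total(self) -> float:
        return self.resource_total + self.drug


def cycle_cost(
    counts: Mapping[str, float],
    schedule: CostSchedule,
    price_30day: float,
    cycle_years: float,
) -> CycleCost:
    """Cost of one cycle: Σ count × unit cost, plus drug supply for the cycle.

    The drug cost is the 30-day price prorated over the cycle's days,
    ``price × 365.25 × cycle_years / 30``; survival weighting is applied by
    the engine, not here.
    """
    if price_30day < 0:
        raise ValueError("price_30day must be non-negative")
    resource = {}
    for cat in RESOURCE_CATEGORIES:
        n = counts.get(cat, 0.0)
        if n < 0:
            raise ValueError(f"negative count for {cat}")
        resource[cat] = n * schedule.unit_cost(cat)
    drug = price_30day * (DAYS_PER_YEAR * cycle_years / 30.0)
    return CycleCost(resource=resource, drug=drug)


# --------------------------------------------------------------------------
# Incremental comparison
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CEComparison:
    """Incremental result of intervention vs comparator.

    ``icer`` is a number only when ΔC and ΔQ share a sign and ΔQ ≠ 0;
    otherwise the ``verdict`` carries the conclusion: ``"dominant"`` (cheaper
    and more effective), ``"dominated"`` (the reverse), or
    ``"no QALY difference"``.
    """

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    delta_ly_discounted: float
    icer: float | None
    verdict: str
    cost_deltas: dict[str, float] = field(default_factory=dict)

    @property
    def icer_or_verdict(self) -> str:
        if self.icer is not None:
            return f"{self.icer:.2f}"
        return self.verdict.capitalize() if self.verdict in ("dominant", "dominated") else self.verdict


def compare_arms(intervention, comparator) -> CEComparison:
    """Incremental comparison of two computed arms (intervention − comparator)."""
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.qalys - comparator.qalys
    dly = intervention.life_years - comparator.life_years
    dlyd = intervention.life_years_discounted - comparator.life_years_discounted
    cost_deltas = {
        k: intervention.costs[k] - comparator.costs.get(k, 0.0)
        for k in intervention.costs
    }

    icer: float | None = None
    if dq > 0 and dc < 0:
        verdict = "dominant"
    elif dq < 0 and dc > 0:
        verdict = "dominated"
    elif dq == 0:
        verdict = "no QALY difference" if dc != 0 else "equivalent"
    else:
        icer = dc / dq
        verdict = "icer"
    return CEComparison(
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dly,
        delta_ly_discounted=dlyd,
        icer=icer,
        verdict=verdict,
        cost_deltas=cost_deltas,
    )


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit wtp × ΔQALY − ΔCost at a willingness-to-pay."""
    if wtp < 0:
        raise ValueError("wtp must be non-negative")
    return wtp * delta_qaly - delta_cost
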