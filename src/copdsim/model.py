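"""Model/Results surface over the simulation engine.

:class:`CostEffectivenessModel` holds a validated run configuration;
``fit()`` executes the deterministic cohort comparison for a scenario and
returns :class:`CEResults` (per-arm totals, the incremental comparison and a
``summary()`` table); ``fit_psa()`` runs the probabilistic sensitivity
analysis and returns :class:`PSAResults` (replicates, acceptability curve,
plotting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .econ import CEComparison, net_monetary_benefit
from .engine import ArmResult, RunConfig, run_scenario, scenario_config
from .psa import CEACCurve, PSADraw, ceac, draws_to_frame, run_psa


class CostEffectivenessModel:
    """Linked-equation COPD progression model for a two-arm comparison."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config

    @classmethod
    def from_config(cls, path: str | Path) -> "CostEffectivenessModel":
        from .config import load_config

        return cls(load_config(path))

    @classmethod
    def base_case(cls, seed: int = 0, **kwargs) -> "CostEffectivenessModel":
        """Reference cohort + documented synthetic default equations."""
        from .synthetic import base_case_config

        return cls(base_case_config(seed=seed, **kwargs))

    def fit(self, scenario: str = "base") -> "CEResults":
        """Deterministic cohort run of one scenario (base, A, B or C)."""
        comparison, arms = run_scenario(scenario, self.config)
        return CEResults(
            comparison=comparison,
            arms=arms,
            config=scenario_config(scenario, self.config),
            scenario=scenario,
        )

    def fit_psa(
        self, n_iterations: int | None = None, seed: int | None = None
    ) -> "PSAResults":
        """Probabilistic sensitivity analysis over both uncertainty orders."""
        draws, excluded = run_psa(self.config, n_iterations=n_iterations, seed=seed)
        return PSAResults(draws=tuple(draws), excluded=excluded, config=self.config)


@dataclass(frozen=True)
class CEResults:
    """Deterministic cost-effectiveness results for one scenario."""

    comparison: CEComparison
    arms: dict[str, ArmResult]
    config: RunConfig
    scenario: str

    @property
    def icer(self) -> float | None:
        return self.comparison.icer

    @property
    def verdict(self) -> str:
        return self.comparison.verdict

    def arm_frame(self) -> pd.DataFrame:
        rows = []
        for key, arm in self.arms.items():
            rows.append(
                {
                    "arm": key,
                    "treatment": arm.name,
                    "total_cost": arm.total_cost,
                    "drug_cost": arm.costs["drug"],
                    "resource_cost": arm.resource_cost,
                    "qalys": arm.qalys,
                    "life_years": arm.life_years,
                    "life_years_discounted": arm.life_years_discounted,
                    "moderate_exacs": arm.moderate_exacs,
                    "severe_exacs": arm.severe_exacs,
                }
            )
        return pd.DataFrame(rows).set_index("arm")

    def summary(self) -> str:
        a = self.arms["intervention"]
        b = self.arms["comparator"]
        c = self.comparison
        lines = [
            f"Cost-effectiveness results — scenario {self.scenario} "
            f"({self.config.horizon} horizon, {self.config.discount_rate:.1%} discount)",
            "=" * 72,
            f"{'':<26}{a.name:>18}{b.name:>18}",
            f"{'total cost (GBP)':<26}{a.total_cost:>18.2f}{b.total_cost:>18.2f}",
            f"{'  drug':<26}{a.costs['drug']:>18.2f}{b.costs['drug']:>18.2f}",
            f"{'  resource use':<26}{a.resource_cost:>18.2f}{b.resource_cost:>18.2f}",
            f"{'QALYs (discounted)':<26}{a.qalys:>18.4f}{b.qalys:>18.4f}",
            f"{'life-years':<26}{a.life_years:>18.4f}{b.life_years:>18.4f}",
            f"{'moderate exacerbations':<26}{a.moderate_exacs:>18.4f}{b.moderate_exacs:>18.4f}",
            f"{'severe exacerbations':<26}{a.severe_exacs:>18.4f}{b.severe_exacs:>18.4f}",
            "-" * 72,
            f"incremental cost:  {c.delta_cost:>12.2f} GBP",
            f"incremental QALYs: {c.delta_qaly:>12.4f}",
            f"incremental LYs:   {c.delta_ly:>12.4f}",
            f"ICER:              {c.icer_or_verdict:>12}"
            + (" GBP/QALY" if c.icer is not None else ""),
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class PSAResults:
    """Probabilistic sensitivity analysis results and acceptability curves."""

    draws: tuple[PSADraw, ...]
    excluded: int
    config: RunConfig

    @property
    def n(self) -> int:
        return len(self.draws)

    def to_frame(self) -> pd.DataFrame:
        return draws_to_frame(self.draws)

    @property
    def mean_delta_cost(self) -> float:
        return float(np.mean([d.delta_cost for d in self.draws]))

    @property
    def mean_delta_qaly(self) -> float:
        return float(np.mean([d.delta_qaly for d in self.draws]))

    def ceac(self, wtp_grid: Sequence[float] | None = None) -> CEACCurve:
        grid = list(wtp_grid) if wtp_grid is not None else self.config.psa.wtp_grid()
        return ceac(self.draws, grid)

    def probability_cost_effective(self, wtp: float) -> float:
        return float(
            np.mean(
                [
                    net_monetary_benefit(d.delta_cost, d.delta_qaly, wtp) > 0
                    for d in self.draws
                ]
            )
        )

    def summary(self, wtp: float = 20_000.0) -> str:
        return "\n".join(
            [
                f"Probabilistic sensitivity analysis ({self.n} replicates"
                + (f", {self.excluded} excluded)" if self.excluded else ")"),
                "=" * 56,
                f"mean incremental cost:  {self.mean_delta_cost:>12.2f} GBP",
                f"mean incremental QALYs: {self.mean_delta_qaly:>12.4f}",
                f"P(cost-effective at {wtp:,.0f}/QALY): "
                f"{self.probability_cost_effective(wtp):.3f}",
            ]
        )

    def plot_ceac(self, ax=None, wtp_grid: Sequence[float] | None = None, **kwargs):
        """Plot the cost-effectiveness acceptability curve on an axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.ceac(wtp_grid).to_frame()
        ax.plot(df["wtp"], df["probability"], **kwargs)
        ax.set_xlabel("willingness to pay (GBP/QALY)")
        ax.set_ylabel("probability cost-effective")
        ax.set_ylim(0, 1.02)
        return ax
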