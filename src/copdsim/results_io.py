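"""Results serialisation: CSV tables plus a reproducible run-metadata file.

``write_results`` emits comparison.csv (one row per scenario run: ΔQALY,
ΔCost, ICER or verdict), arm_trajectories.csv (per-cycle accounting for
both arms), costs_disaggregated.csv, ceac.csv when a PSA was run, and
run_metadata.yaml — a config echo (with seed and package version) that
:func:`copdsim.config.load_config` accepts directly, so every run is
re-runnable from its metadata alone.  Currency is rounded to pennies at
this reporting boundary only; internal arithmetic stays at full precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .config import config_to_dict
from .econ import CEComparison
from .engine import ArmResult, RunConfig
from .psa import CEACCurve, PSADraw, draws_to_frame


def comparison_row(label: str, comparison: CEComparison) -> dict:
    return {
        "scenario": label,
        "delta_qaly": round(comparison.delta_qaly, 6),
        "delta_cost": round(comparison.delta_cost, 2),
        "delta_ly": round(comparison.delta_ly, 6),
        "icer_or_verdict": comparison.icer_or_verdict,
    }


def trajectory_frame(arms: Mapping[str, ArmResult]) -> pd.DataFrame:
    rows = []
    for key, arm in arms.items():
        for rec in arm.trajectory:
            rows.append(
                {
                    "arm": key,
                    "treatment": arm.name,
                    "cycle": rec.cycle,
                    "t_start": rec.t_start,
                    "length": rec.length,
                    "alive_start": rec.alive_start,
                    "alive_end": rec.alive_end,
                    "moderate_events": rec.moderate_events,
                    "severe_events": rec.severe_events,
                    "resource_cost": round(rec.resource_cost, 2),
                    "drug_cost": round(rec.drug_cost, 2),
                    "qalys": rec.qalys,
                    "life_years": rec.life_years,
                    "utility": rec.utility,
                }
            )
    return pd.DataFrame(rows)


def disaggregated_costs_frame(arms: Mapping[str, ArmResult]) -> pd.DataFrame:
    rows = []
    for key, arm in arms.items():
        for cat, value in sorted(arm.costs.items()):
            rows.append({"arm": key, "category": cat, "cost": round(value, 2)})
    return pd.DataFrame(rows)


def write_results(
    out_dir: str | Path,
    config: RunConfig,
    comparisons: Mapping[str, CEComparison],
    arms: Mapping[str, ArmResult],
    ceac_curve: CEACCurve | None = None,
    psa_draws: Sequence[PSADraw] | None = None,
) -> list[Path]:
    """Write the result file set; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    comp = pd.DataFrame([comparison_row(k, c) for k, c in comparisons.items()])
    p = out / "comparison.csv"
    comp.to_csv(p, index=False)
    written.append(p)

    p = out / "arm_trajectories.csv"
    trajectory_frame(arms).to_csv(p, index=False)
    written.append(p)

    p = out / "costs_disaggregated.csv"
    disaggregated_costs_frame(arms).to_csv(p, index=False)
    written.append(p)

    if ceac_curve is not None:
        p = out / "ceac.csv"
        ceac_curve.to_frame().to_csv(p, index=False)
        written.append(p)

    if psa_draws is not None:
        p = out / "psa_draws.csv"
        draws_to_frame(psa_draws).to_csv(p, index=False)
        written.append(p)

    meta = {"copdsim_version": __version__, "seed": config.seed,
            "config": config_to_dict(config)}
    p = out / "run_metadata.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    written.append(p)
    return written
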