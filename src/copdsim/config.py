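"""Run-configuration and coefficient-file parsing, validation, serialisation.

Both file formats are YAML (JSON is a YAML subset and parses too).  The
coefficient file holds one block per equation — outcome, link, mode,
intercept, coefficients and SEs — against a strict schema whose error
messages name the offending key.  The run configuration names the cohort,
the equation set, the two treatment arms, the cost schedule, the horizon
and discounting, and the PSA block; a saved run-metadata file round-trips
through :func:`load_config` so any run can be reproduced from its metadata
alone.
"""

from __future__ import annotations

import math
from dataclasses import asdict, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .econ import CostSchedule, UtilityMapping
from .engine import ACCRUALS, HORIZONS, PSASettings, RunConfig
from .equations import (
    CORE_OUTCOMES,
    RESOURCE_CATEGORIES,
    EquationSpec,
    PatientProfile,
    RiskEquationSet,
)
from .psa import FAMILIES, ParameterDistribution
from .treatment import LIFETIME, TreatmentSpec


class ConfigError(ValueError):
    """A configuration or coefficient file failed validation."""


def _require(d: Mapping, key: str, path: str) -> Any:
    if key not in d:
        raise ConfigError(f"{path}.{key}: required key is missing")
    return d[key]


def _number(value: Any, path: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{path}: expected a number, got {value!r}")
    return float(value)


# --------------------------------------------------------------------------
# Coefficient files
# --------------------------------------------------------------------------

_VALID_OUTCOMES = set(CORE_OUTCOMES) | {
    f"resource_use.{c}" for c in RESOURCE_CATEGORIES
}


def _parse_equation(block: Mapping, idx: int) -> tuple[str, EquationSpec]:
    path = f"equations[{idx}]"
    if not isinstance(block, Mapping):
        raise ConfigError(f"{path}: expected a mapping")
    outcome = _require(block, "outcome", path)
    if outcome not in _VALID_OUTCOMES:
        raise ConfigError(
            f"{path}.outcome: unknown outcome {outcome!r}; expected one of "
            f"{sorted(_VALID_OUTCOMES)}"
        )
    known = {"outcome", "link", "mode", "intercept", "coefficients", "se"}
    for key in block:
        if key not in known:
            raise ConfigError(f"{path}.{key}: unknown key")
    coefs = block.get("coefficients") or {}
    ses = block.get("se") or {}
    for name, mapping in (("coefficients", coefs), ("se", ses)):
        if not isinstance(mapping, Mapping):
            raise ConfigError(f"{path}.{name}: expected a mapping")
        for k, v in mapping.items():
            _number(v, f"{path}.{name}.{k}")
    short = outcome.split(".", 1)[-1]
    try:
        spec = EquationSpec(
            outcome=short,
            link=block.get("link", "identity"),
            mode=block.get("mode", "direct"),
            intercept=_number(block.get("intercept", 0.0), f"{path}.intercept"),
            coefficients={k: float(v) for k, v in coefs.items()},
            se={k: float(v) for k, v in ses.items()},
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    return outcome, spec


def parse_equations(data: Mapping) -> RiskEquationSet:
    """Build a validated :class:`RiskEquationSet` from a parsed document."""
    if not isinstance(data, Mapping) or "equations" not in data:
        raise ConfigError("coefficient file must have a top-level 'equations' list")
    blocks = data["equations"]
    if not isinstance(blocks, list):
        raise ConfigError("equations: expected a list of equation blocks")
    eqs: dict[str, EquationSpec | None] = {}
    res: dict[str, EquationSpec | None] = {}
    for i, block in enumerate(blocks):
        outcome, spec = _parse_equation(block, i)
        target, key = (res, outcome.split(".", 1)[1]) if outcome.startswith(
            "resource_use."
        ) else (eqs, outcome)
        if key in target:
            raise ConfigError(f"equations[{i}]: duplicate outcome {outcome!r}")
        target[key] = spec
    out = RiskEquationSet(equations=eqs, resource_use=res)
    try:
        out.validate_covariates()
    except ValueError as exc:
        raise ConfigError(str(exc)) from None
    return out


def load_equations(source: str | Path) -> RiskEquationSet:
    """Load a coefficient file, or a named built-in set.

    ``"synthetic-default"`` resolves to the package's documented synthetic
    coefficient set; anything else is a path to a YAML/JSON file.
    """
    if str(source) == "synthetic-default":
        from .synthetic import paper_like_equations

        return paper_like_equations()
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"coefficient file {path} does not exist")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_equations(data)


def equations_to_dict(eqs: RiskEquationSet) -> dict:
    blocks = []
    for outcome in CORE_OUTCOMES:
        spec = eqs.equations.get(outcome)
        if spec is not None:
            blocks.append(_spec_block(outcome, spec))
    for cat in RESOURCE_CATEGORIES:
        spec = eqs.resource_use.get(cat)
        if spec is not None:
            blocks.append(_spec_block(f"resource_use.{cat}", spec))
    return {"equations": blocks}


def _spec_block(outcome: str, spec: EquationSpec) -> dict:
    return {
        "outcome": outcome,
        "link": spec.link,
        "mode": spec.mode,
        "intercept": spec.intercept,
        "coefficients": dict(spec.coefficients),
        "se": dict(spec.se),
    }


def save_equations(eqs: RiskEquationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(equations_to_dict(eqs), fh, sort_keys=False)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


def _parse_treatment(block: Mapping, path: str) -> TreatmentSpec:
    if not isinstance(block, Mapping):
        raise ConfigError(f"{path}: expected a mapping")
    duration = block.get("effect_duration", "lifetime")
    if duration == "lifetime":
        duration = LIFETIME
    else:
        duration = _number(duration, f"{path}.effect_duration")
    try:
        return TreatmentSpec(
            name=str(_require(block, "name", path)),
            price_30day=_number(_require(block, "price_30day", path), f"{path}.price_30day"),
            effect_channel=block.get("effect_channel", "fev1"),
            effect_mean=_number(block.get("effect_mean", 0.0), f"{path}.effect_mean"),
            effect_se=_number(block.get("effect_se", 0.0), f"{path}.effect_se"),
            effect_duration=duration,
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def _parse_cohort_distributions(block: Any, path: str):
    if block is None or block == "reference":
        return None  # run_psa resolves this to the reference cohort
    if not isinstance(block, list):
        raise ConfigError(f"{path}: expected 'reference' or a list of parameters")
    out = []
    for i, item in enumerate(block):
        p = f"{path}[{i}]"
        family = _require(item, "family", p)
        if family not in FAMILIES:
            raise ConfigError(f"{p}.family: unknown family {family!r}")
        try:
            out.append(
                ParameterDistribution(
                    name=str(_require(item, "name", p)),
                    family=family,
                    mean=_number(_require(item, "mean", p), f"{p}.mean"),
                    se=_number(item.get("se", 0.0), f"{p}.se"),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"{p}: {exc}") from None
    return tuple(out)


def config_from_dict(data: Mapping, base_dir: Path | None = None) -> RunConfig:
    """Validate a parsed run-configuration document into a :class:`RunConfig`."""
    if not isinstance(data, Mapping):
        raise ConfigError("run configuration must be a mapping")
    if "config" in data:  # run-metadata wrapper
        data = data["config"]

    # cohort / profile
    cohort = data.get("cohort", "reference")
    if cohort == "reference":
        profile = PatientProfile()
    elif isinstance(cohort, Mapping):
        valid = {f.name for f in fields(PatientProfile)}
        unknown = set(cohort) - valid
        if unknown:
            raise ConfigError(f"cohort: unknown profile fields {sorted(unknown)}")
        try:
            profile = PatientProfile(**{k: _number(v, f"cohort.{k}") for k, v in cohort.items()})
        except ValueError as exc:
            raise ConfigError(f"cohort: {exc}") from None
    else:
        raise ConfigError("cohort: expected 'reference' or a mapping of fields")

    # equations
    eq_source = data.get("equations", "synthetic-default")
    if isinstance(eq_source, Mapping):
        equations = parse_equations(eq_source)
    elif str(eq_source) == "synthetic-default":
        equations = load_equations(eq_source)
    else:
        p = Path(str(eq_source))
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        equations = load_equations(p)

    treatments = _require(data, "treatments", "")
    if not isinstance(treatments, Mapping) or set(treatments) != {
        "intervention",
        "comparator",
    }:
        raise ConfigError(
            "treatments: expected exactly the keys 'intervention' and 'comparator'"
        )
    intervention = _parse_treatment(treatments["intervention"], "treatments.intervention")
    comparator = _parse_treatment(treatments["comparator"], "treatments.comparator")

    costs = data.get("costs", {})
    if not isinstance(costs, Mapping):
        raise ConfigError("costs: expected a mapping")
    valid_costs = {f.name for f in fields(CostSchedule)}
    unknown = set(costs) - valid_costs
    if unknown:
        raise ConfigError(f"costs: unknown keys {sorted(unknown)}")
    try:
        schedule = CostSchedule(**{
            k: (_number(v, f"costs.{k}") if k != "currency_year" else str(v))
            for k, v in costs.items()
        })
    except ValueError as exc:
        raise ConfigError(f"costs: {exc}") from None

    util = data.get("utility", {})
    if not isinstance(util, Mapping):
        raise ConfigError("utility: expected a mapping")
    valid_util = {f.name for f in fields(UtilityMapping)}
    unknown = set(util) - valid_util
    if unknown:
        raise ConfigError(f"utility: unknown keys {sorted(unknown)}")
    try:
        utility = UtilityMapping(**{
            k: (str(v) if k == "form" else _number(v, f"utility.{k}"))
            for k, v in util.items()
        })
    except ValueError as exc:
        raise ConfigError(f"utility: {exc}") from None

    horizon = data.get("horizon", "lifetime")
    if horizon not in HORIZONS:
        raise ConfigError(f"horizon: unknown tag {horizon!r}; expected one of {HORIZONS}")
    discount_rate = _number(data.get("discount_rate", 0.035), "discount_rate")
    if discount_rate < 0:
        raise ConfigError("discount_rate: must be non-negative")
    accrual = data.get("accrual", "half_cycle")
    if accrual not in ACCRUALS:
        raise ConfigError(f"accrual: unknown tag {accrual!r}; expected one of {ACCRUALS}")

    psa_block = data.get("psa", {})
    if not isinstance(psa_block, Mapping):
        raise ConfigError("psa: expected a mapping")
    try:
        psa = PSASettings(
            n_iterations=int(psa_block.get("n_iterations", 5000)),
            wtp_max=_number(psa_block.get("wtp_max", 50_000.0), "psa.wtp_max"),
            wtp_step=_number(psa_block.get("wtp_step", 1_000.0), "psa.wtp_step"),
            mode=str(psa_block.get("mode", "cohort")),
            cohort=_parse_cohort_distributions(psa_block.get("cohort"), "psa.cohort"),
            truncate_effect_at_zero=bool(psa_block.get("truncate_effect_at_zero", False)),
        )
    except ValueError as exc:
        raise ConfigError(f"psa: {exc}") from None

    try:
        return RunConfig(
            profile=profile,
            equations=equations,
            intervention=intervention,
            comparator=comparator,
            schedule=schedule,
            utility=utility,
            horizon=horizon,
            discount_rate=discount_rate,
            age_cap=_number(data.get("age_cap", 100.0), "age_cap"),
            seed=int(data.get("seed", 0)),
            accrual=accrual,
            p_cough_sputum0=_number(data.get("p_cough_sputum0", 0.6), "p_cough_sputum0"),
            psa=psa,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration (or run-metadata) file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file {path} does not exist")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data, base_dir=path.parent)


def _treatment_dict(t: TreatmentSpec) -> dict:
    d = asdict(t)
    if math.isinf(d["effect_duration"]):
        d["effect_duration"] = "lifetime"
    return d


def config_to_dict(config: RunConfig) -> dict:
    """Serialise a RunConfig to the document form load_config accepts."""
    psa = config.psa
    return {
        "cohort": asdict(config.profile),
        "equations": equations_to_dict(config.equations),
        "treatments": {
            "intervention": _treatment_dict(config.intervention),
            "comparator": _treatment_dict(config.comparator),
        },
        "costs": asdict(config.schedule),
        "utility": asdict(config.utility),
        "horizon": config.horizon,
        "discount_rate": config.discount_rate,
        "age_cap": config.age_cap,
        "seed": config.seed,
        "accrual": config.accrual,
        "p_cough_sputum0": config.p_cough_sputum0,
        "psa": {
            "n_iterations": psa.n_iterations,
            "wtp_max": psa.wtp_max,
            "wtp_step": psa.wtp_step,
            "mode": psa.mode,
            "truncate_effect_at_zero": psa.truncate_effect_at_zero,
            "cohort": (
                "reference"
                if psa.cohort is None
                else [asdict(p) for p in psa.cohort]
            ),
        },
    }


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
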