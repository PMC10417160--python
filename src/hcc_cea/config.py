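"""Model-configuration loading, validation and strategy construction.

The whole analysis is driven by one structured YAML file (the packaged
``orient32.yaml`` encodes the published input table verbatim).  Loading
validates every invariant at once and reports all violations with their
key paths, so a hand-edited file fails loudly and precisely.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .distributions import SurvivalDistribution
from .markov import AdverseEventSpec, ModelConfig, StrategySpec

__all__ = [
    "SCENARIOS",
    "ConfigError",
    "ModelBundle",
    "load_config",
    "load_default_config",
    "default_config_path",
    "build_strategies",
]

SCENARIOS = ("list_price", "medicare")

#: arm keys in canonical order (intervention first)
ARMS = ("sintilimab_ibi305", "sorafenib")


class ConfigError(ValueError):
    """Raised with one message line per validation failure."""


@dataclass
class ModelBundle:
    """A validated configuration: raw parameter tree plus model settings."""

    raw: dict
    config: ModelConfig

    def copy(self) -> "ModelBundle":
        return ModelBundle(raw=copy.deepcopy(self.raw), config=self.config)

    def strategies(self, scenario: str = "list_price") -> tuple[StrategySpec, StrategySpec]:
        return build_strategies(self, scenario)

    def dump(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=False)


def _check_range(entry: Any, path: str, errors: list[str], lo=None, hi=None) -> None:
    if not isinstance(entry, dict) or not {"value", "low", "high"} <= set(entry):
        errors.append(f"{path}: expected a mapping with value/low/high")
        return
    v, l, h = entry["value"], entry["low"], entry["high"]
    if not all(isinstance(x, (int, float)) for x in (v, l, h)):
        errors.append(f"{path}: value/low/high must be numbers")
        return
    if not l <= v <= h:
        errors.append(f"{path}: requires low <= value <= high, got {l}/{v}/{h}")
    if lo is not None and (v < lo or l < lo):
        errors.append(f"{path}: values must be >= {lo}")
    if hi is not None and (v > hi or h > hi):
        errors.append(f"{path}: values must be <= {hi}")


def _validate(raw: dict) -> list[str]:
    errors: list[str] = []
    for section in ("model", "survival", "costs", "utilities", "adverse_events",
                    "subsequent_treatment"):
        if section not in raw:
            errors.append(f"missing top-level section '{section}'")
    if errors:
        return errors

    model = raw["model"]
    for key in ("cycle_days", "horizon_years", "discount_rate_annual", "wtp"):
        if key not in model:
            errors.append(f"model.{key}: missing")
    if model.get("pd_drug_accrual", "all") not in ("all", "proportional"):
        errors.append("model.pd_drug_accrual: must be 'all' or 'proportional'")
    if not 0 <= model.get("discount_rate_annual", 0) < 1:
        errors.append("model.discount_rate_annual: must be in [0, 1)")

    for arm in ARMS:
        if arm not in raw["survival"]:
            errors.append(f"survival.{arm}: missing")
            continue
        for endpoint in ("os", "pfs"):
            spec = raw["survival"][arm].get(endpoint)
            if not isinstance(spec, dict) or "family" not in spec:
                errors.append(f"survival.{arm}.{endpoint}: needs a 'family' mapping")
                continue
            try:
                SurvivalDistribution(
                    spec["family"], {k: v for k, v in spec.items() if k != "family"}
                )
            except ValueError as exc:
                errors.append(f"survival.{arm}.{endpoint}: {exc}")

    for name, entry in raw["costs"].items():
        _check_range(entry, f"costs.{name}", errors, lo=0)
    for name, entry in raw["utilities"].items():
        _check_range(entry, f"utilities.{name}", errors, lo=0, hi=1)

    ae = raw["adverse_events"]
    for block, bounds in (("costs", dict(lo=0)), ("disutilities", dict(hi=0))):
        for name, entry in ae.get(block, {}).items():
            _check_range(entry, f"adverse_events.{block}.{name}", errors, **bounds)
    for arm, events in ae.get("incidence", {}).items():
        for name, entry in events.items():
            path = f"adverse_events.incidence.{arm}.{name}"
            _check_range(entry, path, errors, lo=0, hi=1)
            if name not in ae.get("costs", {}):
                errors.append(f"{path}: no matching adverse_events.costs.{name}")
            if name not in ae.get("disutilities", {}):
                errors.append(f"{path}: no matching adverse_events.disutilities.{name}")

    sub = raw["subsequent_treatment"]
    if sub.get("drug") not in raw["costs"]:
        errors.append("subsequent_treatment.drug: must name an entry in costs")
    for arm in ARMS:
        p = sub.get("proportion", {}).get(arm)
        if p is None or not 0 <= p <= 1:
            errors.append(f"subsequent_treatment.proportion.{arm}: must be in [0, 1]")
    return errors


def load_config(source: str | Path | io.TextIOBase) -> ModelBundle:
    """Load and validate a model configuration from YAML."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    if not isinstance(raw, dict):
        raise ConfigError("configuration file is empty or not a mapping")
    errors = _validate(raw)
    if errors:
        raise ConfigError(
            "invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors)
        )
    model = raw["model"]
    config = ModelConfig(
        cycle_days=float(model["cycle_days"]),
        horizon_years=float(model["horizon_years"]),
        discount_rate_annual=float(model["discount_rate_annual"]),
        half_cycle_correction=bool(model.get("half_cycle_correction", True)),
        wtp=float(model["wtp"]),
    )
    return ModelBundle(raw=raw, config=config)


def default_config_path() -> Path:
    return Path(str(resources.files("hcc_cea").joinpath("data/orient32.yaml")))


def load_default_config() -> ModelBundle:
    """The packaged two-arm configuration (published input table, 2021 USD)."""
    return load_config(default_config_path())


def _dist(raw_spec: dict) -> SurvivalDistribution:
    return SurvivalDistribution(
        raw_spec["family"], {k: v for k, v in raw_spec.items() if k != "family"}
    )


def _drug_cost(raw: dict, drug: str, scenario: str) -> float:
    costs = raw["costs"]
    if scenario == "medicare" and f"{drug}_medicare" in costs:
        return costs[f"{drug}_medicare"]["value"]
    return costs[drug]["value"]


def build_strategies(
    bundle: ModelBundle, scenario: str = "list_price"
) -> tuple[StrategySpec, StrategySpec]:
    """Construct the two StrategySpecs for a pricing scenario.

    ``scenario`` selects list prices or post-insurance ("medicare")
    prices where the configuration provides them; all other inputs are
    shared.  Returns (intervention, comparator).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    raw = bundle.raw
    costs = raw["costs"]
    sub = raw["subsequent_treatment"]
    ae = raw["adverse_events"]
    accrual = raw["model"].get("pd_drug_accrual", "all")
    admin_arms = raw.get("admin_cost_arms", [])

    def arm(name: str, drug_cost: float) -> StrategySpec:
        events = tuple(
            AdverseEventSpec(
                name=ev,
                incidence=entry["value"],
                one_time_cost=ae["costs"][ev]["value"],
                disutility=ae["disutilities"][ev]["value"],
            )
            for ev, entry in ae["incidence"].get(name, {}).items()
        )
        return StrategySpec(
            name=name,
            os=_dist(raw["survival"][name]["os"]),
            pfs=_dist(raw["survival"][name]["pfs"]),
            drug_cost_sd_per_cycle=drug_cost,
            admin_cost_sd_per_cycle=(
                costs["administration"]["value"] if name in admin_arms else 0.0
            ),
            followup_cost_per_cycle=costs["followup"]["value"],
            lab_cost_per_cycle=costs["laboratory"]["value"],
            subsequent_tx_proportion=sub["proportion"][name],
            subsequent_tx_cost_per_cycle=_drug_cost(raw, sub["drug"], scenario),
            pd_drug_accrual=accrual,
            utility_sd=raw["utilities"]["sd"]["value"],
            utility_pd=raw["utilities"]["pd"]["value"],
            adverse_events=events,
        )

    sb = arm(
        "sintilimab_ibi305",
        _drug_cost(raw, "sintilimab", scenario) + costs["ibi305"]["value"],
    )
    so = arm("sorafenib", _drug_cost(raw, "sorafenib", scenario))
    return sb, so
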