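"""Configuration files, output tables, and run manifests.

Treatment intensity is the classic reproduction hazard here: the
literature quotes it both per cell cycle (sigma) and as daily arrest
(sigma / cycle_days).  The canonical internal unit is the per-cycle
fraction; config files must name the unit via the key
(``sigma_per_cycle`` / ``sigma_daily``) and values may use a percent
suffix ("1.5%").  Bare numbers at or above 0.5 are rejected as ambiguous
(almost certainly percent written as a bare number).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pandas as pd
import yaml

from .params import ModelParams
from .scenarios import ReplicateOutcome, ScenarioConfig, outcomes_to_dataframe
from .summaries import ScenarioSummary

__all__ = [
    "ConfigError",
    "parse_fraction",
    "load_config",
    "write_config",
    "RunManifest",
    "write_outcomes_csv",
    "read_outcomes_csv",
    "write_summary_json",
]


class ConfigError(ValueError):
    """Schema violation in a configuration file, with the field path."""

    def __init__(self, path: str, message: str):
        self.field_path = path
        super().__init__(f"{path}: {message}")


def parse_fraction(value: Union[str, float, int], where: str = "sigma") -> float:
    """Parse a dimensionless fraction, accepting a percent suffix.

    "1.5%" -> 0.015; numeric 0.015 -> 0.015.  Numeric values >= 0.5 are
    rejected: intensities that large are outside the model's regime and
    almost always indicate a percentage typed without its suffix.
    """
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            try:
                return float(text[:-1]) / 100.0
            except ValueError:
                raise ConfigError(where, f"cannot parse percentage {value!r}") from None
        try:
            value = float(text)
        except ValueError:
            raise ConfigError(where, f"cannot parse {value!r}; use a fraction or a '%' suffix") from None
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ConfigError(where, f"expected a number or percentage, got {value!r}") from None
    if out < 0:
        raise ConfigError(where, "fraction must be non-negative")
    if out >= 0.5:
        raise ConfigError(where, f"{out} is ambiguous as a fraction; write it as a percentage, e.g. '1.5%'")
    return out


# Table 1 symbols accepted as aliases for the canonical field names.
_MODEL_ALIASES = {
    "T": "cycle_days",
    "s": "driver_advantage",
    "c": "resistance_cost",
    "u": "driver_mut_rate",
    "v": "resistance_mut_rate",
    "N": "max_extra_drivers",
    "M": "detection_threshold",
    "kappa": "pre_resistance",
}
_MODEL_FIELDS = set(ModelParams.__dataclass_fields__)
_FRACTION_MODEL_FIELDS = {"driver_advantage", "resistance_cost", "pre_resistance"}

_SCENARIO_ALIASES = {"M0": "initial_size"}
_SCENARIO_FIELDS = {
    "kind",
    "initial_size",
    "resistant_fraction",
    "resistant_count",
    "discovery_threshold",
    "residual_size",
    "horizon_years",
    "replicates",
    "base_seed",
    "metronomic",
    "exclude_extinctions",
}


def _resolve_section(raw: dict, aliases: dict, fields: set, section: str) -> dict:
    out: dict = {}
    for key, value in raw.items():
        name = aliases.get(key, key)
        if name not in fields:
            raise ConfigError(f"{section}.{key}", "unknown key")
        if name in out:
            raise ConfigError(f"{section}.{key}", f"duplicates {name}")
        out[name] = value
    return out


def load_config(path: Union[str, Path]) -> Tuple[ModelParams, ScenarioConfig]:
    """Load a YAML config with ``model`` and ``scenario`` sections.

    Unspecified model fields fall back to the baseline values, except the
    driver cap N (``max_extra_drivers``), which must be stated explicitly:
    published results use N = 5 or N = 9 depending on the protocol, so a
    silent default would be a trap.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("<root>", "config must be a mapping")
    unknown = set(raw) - {"model", "scenario"}
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown top-level section")

    model_raw = raw.get("model") or {}
    scen_raw = raw.get("scenario") or {}
    model_kw = _resolve_section(model_raw, _MODEL_ALIASES, _MODEL_FIELDS, "model")
    for name in _FRACTION_MODEL_FIELDS & set(model_kw):
        model_kw[name] = parse_fraction(model_kw[name], f"model.{name}")
    for name, value in model_kw.items():
        # YAML reads literals like 1e-5 as strings; coerce to field types
        if name in ("max_extra_drivers", "detection_threshold"):
            model_kw[name] = int(float(value))
        elif not isinstance(value, float):
            try:
                model_kw[name] = float(value)
            except (TypeError, ValueError):
                raise ConfigError(f"model.{name}", f"expected a number, got {value!r}") from None
    if "max_extra_drivers" not in model_kw:
        raise ConfigError("model.max_extra_drivers", "N must be given explicitly (5 or 9)")
    try:
        params = ModelParams(**model_kw)
    except ValueError as exc:
        raise ConfigError("model", str(exc)) from exc

    scen_kw = _resolve_section(scen_raw, _SCENARIO_ALIASES, _SCENARIO_FIELDS | {"sigma_per_cycle", "sigma_daily"}, "scenario")
    if "sigma_per_cycle" in scen_kw and "sigma_daily" in scen_kw:
        raise ConfigError("scenario.sigma_daily", "give sigma_per_cycle or sigma_daily, not both")
    sigma = 0.0
    if "sigma_per_cycle" in scen_kw:
        sigma = parse_fraction(scen_kw.pop("sigma_per_cycle"), "scenario.sigma_per_cycle")
    elif "sigma_daily" in scen_kw:
        sigma = parse_fraction(scen_kw.pop("sigma_daily"), "scenario.sigma_daily") * params.cycle_days
    if "kind" not in scen_kw:
        raise ConfigError("scenario.kind", "scenario kind is required")
    if "resistant_fraction" in scen_kw and scen_kw["resistant_fraction"] is not None:
        scen_kw["resistant_fraction"] = parse_fraction(
            scen_kw["resistant_fraction"], "scenario.resistant_fraction"
        )
    try:
        config = ScenarioConfig(sigma=sigma, **scen_kw)
    except (ValueError, TypeError) as exc:
        raise ConfigError("scenario", str(exc)) from exc
    return params, config


def write_config(params: ModelParams, config: ScenarioConfig, path: Union[str, Path]) -> None:
    """Serialise a (params, config) pair so load_config round-trips it."""
    doc = {
        "model": asdict(params),
        "scenario": {
            "kind": config.kind.value,
            "sigma_per_cycle": config.sigma,
            "initial_size": config.initial_size,
            "resistant_fraction": config.resistant_fraction,
            "resistant_count": config.resistant_count,
            "discovery_threshold": config.discovery_threshold,
            "residual_size": config.residual_size,
            "horizon_years": config.horizon_years,
            "replicates": config.replicates,
            "base_seed": config.base_seed,
            "metronomic": config.metronomic,
            "exclude_extinctions": config.exclude_extinctions,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    command: str
    package_version: str
    base_seed: int
    seed_rule: str
    model: dict
    scenario: dict
    outputs: List[str] = field(default_factory=list)
    created_utc: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def write_outcomes_csv(outcomes: Iterable[ReplicateOutcome], path: Union[str, Path]) -> None:
    outcomes_to_dataframe(outcomes).to_csv(path, index=False)


def read_outcomes_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ConfigError(str(path), "outcome file contains no replicates")
    return df


def write_summary_json(summary: ScenarioSummary, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
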