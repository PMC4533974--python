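"""TOML configuration files mirroring :class:`SimulationConfig`.

The dialect is flat TOML, field-for-field with the config dataclass; the
extinction schedule is expressed as ``schedule = "none" | "fixed" |
"random_uniform"`` plus its interval fields::

    grid_width = 101
    grid_height = 101
    niche_capacity = 10
    offspring_per_parent = 2
    initial_evolvability = 0.025
    evolvability_mutation_rate = 0.005
    evolvability_perturbation_half_width = 0.0025
    generations = 3000
    severity = 5
    rng_seed = 1
    schedule = "fixed"
    interval = 200
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .errors import ConfigurationError
from .model import SimulationConfig
from .schedule import ExtinctionSchedule

__all__ = ["load_config", "save_config"]

_SCALAR_FIELDS = (
    "grid_width",
    "grid_height",
    "niche_capacity",
    "offspring_per_parent",
    "initial_evolvability",
    "evolvability_mutation_rate",
    "evolvability_perturbation_half_width",
    "generations",
    "severity",
    "rng_seed",
)
_SCHEDULE_FIELDS = ("schedule", "interval", "min_interval", "max_interval")


def _schedule_from_mapping(data: dict) -> ExtinctionSchedule:
    variant = data.get("schedule", "none")
    if variant == "none":
        return ExtinctionSchedule.none()
    if variant == "fixed":
        if "interval" not in data:
            raise ConfigurationError("fixed schedule requires 'interval'")
        return ExtinctionSchedule.fixed(data["interval"])
    if variant == "random_uniform":
        if "min_interval" not in data or "max_interval" not in data:
            raise ConfigurationError(
                "random_uniform schedule requires 'min_interval' and 'max_interval'"
            )
        return ExtinctionSchedule.random_uniform(data["min_interval"], data["max_interval"])
    raise ConfigurationError(f"unknown schedule {variant!r}")


def load_config(path, **overrides) -> SimulationConfig:
    """Read a TOML config file; keyword overrides win over file values."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    unknown = set(data) - set(_SCALAR_FIELDS) - set(_SCHEDULE_FIELDS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    kwargs = {k: data[k] for k in _SCALAR_FIELDS if k in data}
    if "extinction_schedule" in overrides and overrides["extinction_schedule"] is not None:
        kwargs["extinction_schedule"] = overrides["extinction_schedule"]
    else:
        kwargs["extinction_schedule"] = _schedule_from_mapping(data)
    return SimulationConfig(**kwargs)


def save_config(config: SimulationConfig, path) -> None:
    """Write a config as flat TOML in the documented dialect."""
    lines = []
    for name in _SCALAR_FIELDS:
        value = getattr(config, name)
        lines.append(f"{name} = {value!r}" if isinstance(value, float) else f"{name} = {value}")
    sched = config.extinction_schedule
    lines.append(f'schedule = "{sched.variant}"')
    if sched.variant == "fixed":
        lines.append(f"interval = {sched.interval}")
    elif sched.variant == "random_uniform":
        lines.append(f"min_interval = {sched.min_interval}")
        lines.append(f"max_interval = {sched.max_interval}")
    Path(path).write_text("\n".join(lines) + "\n")
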