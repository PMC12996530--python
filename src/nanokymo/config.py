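"""Strict-schema YAML run configuration.

One hierarchical document drives the CLI; unknown keys are rejected so a
typo cannot silently fall back to a default, and every stochastic stage
carries an explicit seed that is logged with the resolved parameters.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .hvit import ArchConfig, SimConfig, TrainConfig
from .simulate import ChannelGeometry, NoiseParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for schema violations in a run-configuration document."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved run configuration for the pipeline commands."""

    seed: int = 0
    geometry: ChannelGeometry = field(
        default_factory=lambda: ChannelGeometry(width_nm=63.0, depth_nm=30.0)
    )
    noise: NoiseParams = field(default_factory=NoiseParams)
    arch: ArchConfig = field(default_factory=ArchConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    simulate: dict = field(default_factory=lambda: dict(DEFAULT_SIMULATE))

    def sim_config(self) -> SimConfig:
        return SimConfig(geometry=self.geometry, noise=self.noise,
                         gaussian_width_nm=self.simulate["gaussian_width_nm"])


DEFAULT_SIMULATE = {
    "n": 24,
    "frames": 512,
    "mw_range_kda": [1.0, 30.0],
    "rs_range_nm": [0.7, 3.0],
    "gaussian_width_nm": 300.0,
    "seed": 0,
}

_SECTION_TYPES = {
    "geometry": ChannelGeometry,
    "noise": NoiseParams,
    "arch": ArchConfig,
    "train": TrainConfig,
}


def _build_section(cls, data: dict, section: str):
    import dataclasses

    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in section '{section}': {sorted(unknown)}"
        )
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML document; ``None`` yields all defaults."""
    if path is None:
        cfg = RunConfig()
    else:
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        if not isinstance(doc, dict):
            raise ConfigError("top level of the config must be a mapping")
        allowed = {"seed", "simulate"} | set(_SECTION_TYPES)
        unknown = set(doc) - allowed
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "seed" in doc:
            if not isinstance(doc["seed"], int):
                raise ConfigError("seed must be an integer")
            kwargs["seed"] = doc["seed"]
        for section, cls in _SECTION_TYPES.items():
            if section in doc:
                if not isinstance(doc[section], dict):
                    raise ConfigError(f"section '{section}' must be a mapping")
                kwargs[section] = _build_section(cls, doc[section], section)
        if "simulate" in doc:
            sim = dict(DEFAULT_SIMULATE)
            unknown = set(doc["simulate"]) - set(sim)
            if unknown:
                raise ConfigError(
                    f"unknown keys in section 'simulate': {sorted(unknown)}"
                )
            sim.update(doc["simulate"])
            kwargs["simulate"] = sim
        cfg = RunConfig(**kwargs)
    logger.info("resolved configuration: %s", asdict_safe(cfg))
    return cfg


def asdict_safe(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d
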