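"""Pipeline configuration: one YAML file drives generate / clean / stats.

Unknown keys are rejected everywhere — a typo in a rate name must fail
loudly, not silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .synthetic import GeneratorConfig
from .treatment import DEFAULT_ORDER


@dataclass
class CleanOptions:
    order: tuple[str, ...] = DEFAULT_ORDER
    year_span: int | None = None  # frequency-screen threshold; None = from data
    rounding: int = 2


@dataclass
class StatsOptions:
    situations: tuple[str, ...] = ("B", "D")
    bonferroni: bool = False


@dataclass
class PipelineConfig:
    generate: GeneratorConfig = field(default_factory=GeneratorConfig)
    clean: CleanOptions = field(default_factory=CleanOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    out_dir: str = "out"


def _build(cls, data: Mapping[str, Any], context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"{context}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    coerced = {}
    for key, value in data.items():
        coerced[key] = tuple(value) if isinstance(value, list) else value
    return cls(**coerced)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration file, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    allowed = {"generate", "clean", "stats", "out_dir"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    config = PipelineConfig(
        generate=_build(GeneratorConfig, data.get("generate", {}) or {}, "generate"),
        clean=_build(CleanOptions, data.get("clean", {}) or {}, "clean"),
        stats=_build(StatsOptions, data.get("stats", {}) or {}, "stats"),
        out_dir=str(data.get("out_dir", "out")),
    )
    config.generate.validate()
    return config
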