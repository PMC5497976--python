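"""TOML run configuration.

One file with sections ``[spectral]``/``[detection]``, ``[features]``,
``[classify]``, ``[evaluate]`` and ``[simulate]`` maps onto the parameter
dataclasses of the corresponding modules. Every key has a default; unknown
keys are rejected so typos fail loudly. Values can be overridden from the
command line with dotted ``section.key=value`` strings.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .baseline import TemplateMatchConfig
from .features import FeatureConfig
from .islands import DetectionConfig
from .simulate import SimConfig

__all__ = ["ClassifyConfig", "EvaluateConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class ClassifyConfig:
    n_trees: int = 500
    max_features: str = "sqrt"
    neighborhood_radius_s: float = 7.5
    cutoff: float = 0.5


@dataclass(frozen=True)
class EvaluateConfig:
    min_overlap_s: float = 0.050
    rate_bandwidth_s: float = 60.0
    target_capture: float = 0.95


@dataclass
class RunConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    simulate: SimConfig = field(default_factory=SimConfig)
    baseline: TemplateMatchConfig = field(default_factory=TemplateMatchConfig)
    seed: int = 0


_SECTION_TYPES = {
    "detection": DetectionConfig,
    # [spectral] keys live on DetectionConfig (band edge, bandwidth, overlap)
    "spectral": DetectionConfig,
    "features": FeatureConfig,
    "classify": ClassifyConfig,
    "evaluate": EvaluateConfig,
    "simulate": SimConfig,
    "baseline": TemplateMatchConfig,
}


def _coerce(value, target_type):
    if dataclasses.is_dataclass(target_type):
        raise TypeError("nested dataclass keys are not settable")
    if isinstance(value, list):
        return tuple(value)
    return value


def _build_section(cls, data: dict, section: str):
    valid = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(valid)
    if unknown:
        raise KeyError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}"
        )
    return cls(**{k: _coerce(v, valid[k].type) for k, v in data.items()})


def load_config(
    path: str | Path | None = None,
    overrides: list[str] | None = None,
) -> RunConfig:
    """Build a :class:`RunConfig` from an optional TOML file plus dotted
    ``section.key=value`` overrides."""
    data: dict = {}
    if path is not None:
        with open(Path(path), "rb") as fh:
            data = tomllib.load(fh)
    for ov in overrides or []:
        if "=" not in ov or "." not in ov.split("=", 1)[0]:
            raise ValueError(f"override must look like section.key=value: {ov!r}")
        key, raw = ov.split("=", 1)
        section, name = key.split(".", 1)
        data.setdefault(section, {})[name] = tomllib.loads(f"v = {raw}")["v"]
    seed = int(data.pop("seed", 0))
    unknown = set(data) - set(_SECTION_TYPES)
    if unknown:
        raise KeyError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    merged: dict[str, dict] = {}
    for section, content in data.items():
        canonical = "detection" if section == "spectral" else section
        merged.setdefault(canonical, {}).update(content)
    kwargs = {}
    for section, content in merged.items():
        kwargs[section] = _build_section(_SECTION_TYPES[section], content, section)
    return RunConfig(seed=seed, **kwargs)
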