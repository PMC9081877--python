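"""Hierarchical pipeline configuration with YAML round-trip.

Every field has a default; unknown keys in a YAML file are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .irrd.loss import LossConfig
from .irrd.network import NetworkConfig
from .irrd.train import TrainConfig
from .postprocess import PostprocessConfig
from .segmentation import SegmentationConfig
from .synthetic import SceneConfig


@dataclass
class MetricConfig:
    """Evaluation parameters: consensus threshold, match tolerance
    (fraction of the image diagonal) and the binarisation threshold grid."""

    eta: float = 0.5
    tol_frac: float = 0.0075
    n_thresholds: int = 33


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)
    seed: int = 0
    output_dir: str = "dewquant_out"


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping, got {data!r}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path or cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = _SECTION_TYPES.get((cls, name))
        if sub is not None:
            kwargs[name] = _from_dict(sub, value, f"{path}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    (PipelineConfig, "segmentation"): SegmentationConfig,
    (PipelineConfig, "network"): NetworkConfig,
    (PipelineConfig, "loss"): LossConfig,
    (PipelineConfig, "training"): TrainConfig,
    (PipelineConfig, "postprocess"): PostprocessConfig,
    (PipelineConfig, "metrics"): MetricConfig,
    (PipelineConfig, "scene"): SceneConfig,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML, with optional overrides.

    ``overrides`` is a nested dict merged on top of the file contents
    (CLI flags win over file values).
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(data.get(key), dict):
            data[key] = {**data[key], **value}
        else:
            data[key] = value
    return _from_dict(PipelineConfig, data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
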