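"""Pipeline configuration: nested dataclasses with strict YAML round-tripping.

Unknown keys are rejected on load so a typo in a config file fails loudly
instead of silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .field_model import FieldConfig, HashGridConfig
from .mesh_extract import MeshConfig
from .render_train import TrainConfig

__all__ = [
    "SceneConfig",
    "KeyframeConfig",
    "PipelineConfig",
    "config_from_dict",
    "config_to_dict",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class SceneConfig:
    """Synthetic-capture stage parameters."""

    n_per_ring: int = 20
    height: int = 64
    width: int = 64
    n_quad: int = 128
    n_leaves: int = 12
    n_heldout: int = 1
    # emulate SfM's arbitrary frame: perturb true poses by a seeded similarity
    perturb_similarity: bool = True


@dataclass(frozen=True)
class KeyframeConfig:
    target_per_view: int = 50
    per_view: int = 45
    rel_threshold: float = 0.2
    max_removed: int = 10


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for an end-to-end run (simulate -> evaluate)."""

    out_dir: str = "runs/demo"
    seed: int = 0
    simulate: bool = True
    scene: SceneConfig = dc_field(default_factory=SceneConfig)
    keyframes: KeyframeConfig = dc_field(default_factory=KeyframeConfig)
    train: TrainConfig = dc_field(default_factory=TrainConfig)
    mesh: MeshConfig = dc_field(default_factory=MeshConfig)


def config_from_dict(cls, data: dict):
    """Build a (possibly nested) config dataclass, rejecting unknown keys."""
    if not dataclasses.is_dataclass(cls):
        raise TypeError(f"{cls} is not a dataclass")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        nested = _nested_class(fields[name])
        if nested is not None and isinstance(value, dict):
            kwargs[name] = config_from_dict(nested, value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _nested_class(f: dataclasses.Field):
    default = (
        f.default_factory()
        if f.default_factory is not dataclasses.MISSING
        else f.default
    )
    return type(default) if dataclasses.is_dataclass(default) else None


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(PipelineConfig, data)


def dump_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
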