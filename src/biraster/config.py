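"""Run configuration: YAML-backed stage configs with seed substreams.

A :class:`RunConfig` merges built-in defaults, a YAML file and explicit
overrides (later wins), and hands each pipeline stage a named seed
substream derived from the single global seed, so no stage consumes
ambient randomness and a saved config re-runs identically.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import yaml

from .core import JitterModel, ScanGeometry
from .losses import LossWeights
from .model import DiscriminatorConfig, GeneratorConfig
from .training import TrainConfig

__all__ = ["RunConfig", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _dataclass_from(cls, mapping: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: v for k, v in mapping.items() if k in fields}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclasses.dataclass
class RunConfig:
    """All stage configurations plus the global seed and output directory."""

    seed: int = 0
    out_dir: str = "runs/default"
    n_pairs: int = 200
    crop_size: int = 192
    crops_per_scene: int = 1
    noise_sigma: float = 0.0045
    ref_pixel_um: float = 1.0
    test_frac: float = 0.2
    val_frac: float = 0.1
    geometry: ScanGeometry = dataclasses.field(default_factory=ScanGeometry)
    jitter: JitterModel = dataclasses.field(default_factory=JitterModel)
    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = dataclasses.field(
        default_factory=DiscriminatorConfig
    )
    training: TrainConfig = dataclasses.field(default_factory=TrainConfig)

    _NESTED = {
        "geometry": ScanGeometry,
        "jitter": JitterModel,
        "generator": GeneratorConfig,
        "discriminator": DiscriminatorConfig,
        "training": TrainConfig,
    }

    @classmethod
    def load(cls, yaml_path=None, **overrides) -> "RunConfig":
        """Build a config: defaults < YAML file < keyword overrides."""
        data: dict = {}
        if yaml_path:
            with open(yaml_path) as f:
                data.update(yaml.safe_load(f) or {})
        for k, v in overrides.items():
            if v is None:
                continue
            if k in cls._NESTED and isinstance(v, dict):
                data.setdefault(k, {}).update(v)
            else:
                data[k] = v
        kwargs = {}
        for k, v in data.items():
            if k in cls._NESTED:
                if k == "training" and isinstance(v, dict) and "loss_weights" in v:
                    v = dict(v)
                    v["loss_weights"] = _dataclass_from(LossWeights, v["loss_weights"])
                kwargs[k] = _dataclass_from(cls._NESTED[k], v)
            else:
                kwargs[k] = v
        return _dataclass_from(cls, kwargs)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {k: conv(getattr(self, k)) for k in (f.name for f in dataclasses.fields(self))}

    def save(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def config_hash(self) -> str:
        return f"{zlib.crc32(json.dumps(self.to_dict(), sort_keys=True).encode()):08x}"
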