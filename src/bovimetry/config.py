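"""YAML-backed pipeline configuration with strict key checking."""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, fields, is_dataclass

import yaml

from .errors import ConfigError
from .measure import MeasureConfig
from .preprocess import FilterParams
from .segment import SegmentParams
from .synth import SceneConfig


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed by stable name hashing,
    so any stage can be rerun in isolation and still reproduce."""
    return (int(seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """All module parameter blocks plus the master seed and stage toggles."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    filters: FilterParams = field(default_factory=FilterParams)
    segmentation: SegmentParams = field(default_factory=SegmentParams)
    curvature_knn: int = 16
    fpfh_radius: float = 0.10
    chest_cylinder_radius: float = 0.03
    use_classifier_gate: bool = False
    seed: int = 0

    def measure_config(self) -> MeasureConfig:
        return MeasureConfig(
            filters=self.filters, segmentation=self.segmentation,
            curvature_knn=self.curvature_knn, fpfh_radius=self.fpfh_radius,
            chest_cylinder_radius=self.chest_cylinder_radius,
            use_classifier_gate=self.use_classifier_gate, seed=self.seed)

    def to_dict(self) -> dict:
        def conv(obj):
            if is_dataclass(obj):
                return {f.name: conv(getattr(obj, f.name))
                        for f in fields(obj)}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj
        return conv(self)


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = allowed[name].type
        target = {"scene": SceneConfig, "filters": FilterParams,
                  "segmentation": SegmentParams}.get(name)
        if target is not None:
            kwargs[name] = _build(target, value, f"{path}.{name}")
        elif name == "ranges" and isinstance(value, dict):
            kwargs[name] = {int(k): tuple(v) for k, v in value.items()}
        else:
            kwargs[name] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


def load_config(path: str | None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML; unknown keys are rejected."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(PipelineConfig, data, "config")
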