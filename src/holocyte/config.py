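"""Pipeline configuration: one document drives every stage.

Defaults mirror the published workflow parameters: minimum object size
26 px, 0.635 um laser wavelength, refractive-index difference 0.04,
BgSD gate 0.5, bootstrap size 1000 per class, Savitzky-Golay degree 2 /
window 5.  Each CLI run writes the fully resolved config (plus seed)
next to its outputs so every artifact is reproducible from config +
seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class SegmentationConfig:
    threshold_mode: str = "otsu"  # "otsu" or "fixed"
    fixed_threshold: float | None = None  # radians, used when mode == "fixed"
    min_size_px: int = 26


@dataclass
class CalibrationConfig:
    wavelength_um: float = 0.635
    delta_n: float = 0.04
    pixel_size_um: float = 0.5
    unit_scale: float = 1.0  # instrument units -> radians on import


@dataclass
class QualityConfig:
    max_bgsd: float = 0.5


@dataclass
class ClassifierConfig:
    n_per_class: int = 1000
    n_dims: str | int = "auto"  # min(3, K-1)
    n_init: int = 10
    tol: float = 1e-6


@dataclass
class KineticsConfig:
    sg_degree: int = 2
    sg_window: int = 5
    max_step_um: float = 20.0
    hypermotility_factor: float = 2.0  # x median hourly displacement of control


@dataclass
class PipelineConfig:
    seed: int = 0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def write_resolved(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "resolved_config.json"
        path.write_text(json.dumps(self.resolved(), indent=1))
        return path


def _merge(cfg, data: dict):
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key: {key}")
        current = getattr(cfg, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _merge(current, value)
        else:
            setattr(cfg, key, value)
    return cfg


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file; keyword overrides win over the file."""
    cfg = PipelineConfig()
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        _merge(cfg, data)
    if overrides:
        _merge(cfg, overrides)
    return cfg
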