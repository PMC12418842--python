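"""Pipeline configuration: one structured YAML file, per-stage sections.

All seeds are explicit (no wall-clock seeding); the canonical serialization
is hashed so every output table can record which configuration produced it
and mismatched re-runs are detectable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ImagingConfig", "SegmentationConfig",
           "StatsConfig", "ClassifierConfig", "load_config", "save_config"]


@dataclass
class ImagingConfig:
    gp_ref: float = 0.6
    gp_mes: float = 0.6          # equal to gp_ref -> G = 1 (unbiased detector)
    n_vesicles: int = 50
    calibration_noise_sd: float = 0.02
    intensity_floor: float = 0.0
    gp_range_low: float = -1.0
    gp_range_high: float = 1.0
    brightness_percentile: float = 99.0
    n_cells_per_group: int = 20
    photon_budget: float = 2000.0
    background_rate: float = 20.0


@dataclass
class SegmentationConfig:
    min_roi_px: int = 50
    ring_width: int = 3
    keep_border: bool = False


@dataclass
class StatsConfig:
    variance_model: str = "auto"   # pooled | welch | auto (F-test gated)
    alpha: float = 0.05


@dataclass
class ClassifierConfig:
    gp_threshold_low: float = 60.27
    gp_threshold_high: float = 66.775
    cv_folds: int = 0              # 0 = training accuracy only


@dataclass
class PipelineConfig:
    seed: int = 0
    run_gp_stage: bool = True
    run_expression_stage: bool = True
    run_marker_stage: bool = True
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sections = {
        "imaging": ImagingConfig, "segmentation": SegmentationConfig,
        "stats": StatsConfig, "classifier": ClassifierConfig,
    }
    kwargs: dict = {}
    for key, val in raw.items():
        if key in sections:
            kwargs[key] = sections[key](**(val or {}))
        else:
            kwargs[key] = val
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
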