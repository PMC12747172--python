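"""Structured pipeline configuration with strict key validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SpectralFitConfig:
    welch_window_s: float = 60.0
    sg_frame_bins: int = 11
    min_prominence_db: float = 0.5
    cqi_relax_step: float = 0.05
    hr_search_range_hz: tuple[float, float] = (0.5, 3.5)


@dataclass
class ScalogramConfig:
    voices_per_octave: int = 12
    fmin_hz: float = 0.2
    fmax_hz: float = 5.0
    target_row: int = 30


@dataclass
class ThresholdConfig:
    cv_threshold: float = 15.0
    sci_threshold: float = 0.75
    psp_threshold: float = 0.1
    cqi_window_s: float = 5.0


@dataclass
class ClassifierConfig:
    lr: float = 1e-4
    batch: int = 32
    max_epochs: int = 50
    l2: float = 1e-4
    patience: int = 15
    input_size: int = 112
    augment: bool = True


@dataclass
class PipelineConfig:
    inputs: list[str] = field(default_factory=list)
    format: str = "snirf"
    fs: float | None = None
    n_segments: int = 5
    spectral_fit: SpectralFitConfig = field(default_factory=SpectralFitConfig)
    scalogram: ScalogramConfig = field(default_factory=ScalogramConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    output_dir: str = "nirsqc_out"
    seed: int = 0
    verbosity: str = "info"

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SECTION_TYPES = {
    "spectral_fit": SpectralFitConfig,
    "scalogram": ScalogramConfig,
    "classifier": ClassifierConfig,
    "thresholds": ThresholdConfig,
}


def _build(cls, data: dict, context: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config keys in {context}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES and isinstance(value, dict):
            kwargs[key] = _build(_SECTION_TYPES[key], value, f"{context}.{key}")
        elif key == "hr_search_range_hz" and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None, overrides: dict | None = None) -> PipelineConfig:
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(raw)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return _build(PipelineConfig, data, "config")
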