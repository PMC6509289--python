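"""Pipeline configuration: a flat, YAML-serialisable record of every knob.

A config fully determines a run: with the same config (including seed)
the pipeline produces byte-identical result tables.  Configs round-trip
losslessly through ``to_dict``/``from_dict`` and YAML files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

from .exceptions import ConfigError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # --- inputs (single-image analysis mode; all None => synthetic study mode)
    image_path: Optional[str] = None
    timing_path: Optional[str] = None
    reference_centre_mm: Optional[Tuple[float, float, float]] = None
    reference_volume_cm3: float = 0.014

    # --- basis grid / fit
    theta_min: float = 0.05
    theta_max: float = 0.4
    n_bases: int = 100
    spacing: str = "log"
    weights: str = "uniform"

    # --- iso-contour segmentation
    threshold_fraction: float = 0.5
    threshold_absolute: Optional[float] = None
    connectivity: int = 26
    lesion_search_centre_mm: Optional[Tuple[float, float, float]] = None
    lesion_search_radius_mm: float = 6.0

    # --- baseline normalisation and statistics
    baseline_day: float = 30
    normalization_mode: str = "ratio"

    # --- synthetic study simulation (study mode)
    n_per_group: int = 4
    days: Tuple[float, ...] = (30, 44, 65, 86, 142)
    sigma_animal: float = 0.12
    sigma_resid: float = 0.12
    rebound_amplitude: float = 0.55
    baseline_bp: float = 1.5
    noise_sigma0: float = 0.2
    study_shape: Tuple[int, int, int] = (32, 32, 20)
    study_voxel_size_mm: float = 0.5
    study_lesion_centre_mm: Tuple[float, float, float] = (5.0, 8.0, 5.0)
    study_lesion_radius_mm: float = 2.0

    # --- run control
    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"

    @property
    def image_mode(self) -> bool:
        return self.image_path is not None

    def validate(self) -> "PipelineConfig":
        """Check consistency and input existence before any computation."""
        if self.spacing not in ("log", "linear"):
            raise ConfigError(f"spacing must be log or linear, got {self.spacing!r}")
        if not (0 < self.theta_min < self.theta_max):
            raise ConfigError("require 0 < theta_min < theta_max")
        if self.normalization_mode not in ("ratio", "difference"):
            raise ConfigError(f"unknown normalisation mode {self.normalization_mode!r}")
        if self.image_mode:
            for label, p in (("image", self.image_path), ("timing", self.timing_path)):
                if p is None:
                    raise ConfigError(f"image mode needs a {label} path")
                if not Path(p).exists():
                    raise ConfigError(f"{label} path does not exist: {p}")
            if self.reference_centre_mm is None:
                raise ConfigError("image mode needs a reference VOI centre (mm)")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in (
            "reference_centre_mm",
            "lesion_search_centre_mm",
            "days",
            "study_shape",
            "study_lesion_centre_mm",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        if not Path(path).exists():
            raise ConfigError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)
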