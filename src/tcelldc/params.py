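"""Parameter containers for the simulator, the video pipeline and training.

All containers are plain dataclasses with validated defaults and a flat
key=value serialization so a single YAML config file can drive the CLI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import yaml

__all__ = [
    "Condition",
    "SimParams",
    "PipelineParams",
    "TrainConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class Condition:
    """Experimental condition of one simulated field.

    A field is a single co-culture well: every T cell in it shares the
    same label and the same antibody treatment.
    """

    label: str  # "cognate" | "non-cognate"
    acd40: bool = False

    def __post_init__(self) -> None:
        if self.label not in ("cognate", "non-cognate"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class SimParams:
    """Parameters of the agent-based interaction-video simulator.

    Lengths are in pixels, durations in minutes, speeds in um/min.
    """

    field_px: int = 320
    pixel_size: float = 1.0          # um per pixel
    frame_interval: float = 2.0      # minutes between frames
    n_frames: int = 45
    n_tcells: int = 8
    n_dcs: int = 6
    tcell_radius: float = 5.0
    dc_radius: float = 9.0
    speed_free: Tuple[float, float] = (3.0, 0.7)  # (mean, sd) um/min
    speed_dc: float = 1.0
    persistence: float = 0.7         # directional persistence in [0, 1]
    capture_radius: float = 24.0     # center-to-center contact distance, px
    dwell_mean_cognate: float = 40.0
    dwell_mean_noncognate: float = 3.0
    arrest_speed_factor: float = 0.2
    contact_circ_cognate: float = 0.45
    contact_circ_noncognate: float = 0.85
    acd40_overlap_gain: float = 1.4
    acd40_noncog_dwell_factor: float = 0.5
    noise_sd: float = 2.0
    start_near_dc: bool = False      # place T cells close to a DC at t=0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.speed_free, list):
            self.speed_free = tuple(self.speed_free)
        self.validate()

    def validate(self) -> None:
        positive = {
            "field_px": self.field_px,
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "n_frames": self.n_frames,
            "tcell_radius": self.tcell_radius,
            "dc_radius": self.dc_radius,
            "capture_radius": self.capture_radius,
            "dwell_mean_cognate": self.dwell_mean_cognate,
            "dwell_mean_noncognate": self.dwell_mean_noncognate,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.field_px < 2 * 101:
            raise ValueError("field_px must be at least 202 to fit crop windows")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
        if not 0.0 <= self.arrest_speed_factor <= 1.0:
            raise ValueError("arrest_speed_factor must lie in [0, 1]")
        for name in ("contact_circ_cognate", "contact_circ_noncognate"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.acd40_overlap_gain < 1.0:
            raise ValueError("acd40_overlap_gain must be >= 1")
        if self.acd40_noncog_dwell_factor > 1.0:
            raise ValueError("acd40_noncog_dwell_factor must be <= 1")


@dataclass
class PipelineParams:
    """Parameters of the per-cell video-processing pipeline."""

    crop_px: int = 101
    target_frames: int = 20
    blur_sigma: float = 1.0
    sampling_mode: str = "uniform"   # "uniform" | "consecutive_k"
    consecutive_k: int = 20
    min_track_frames: int = 20

    def __post_init__(self) -> None:
        if self.crop_px % 2 == 0:
            raise ValueError("crop_px must be odd")
        if self.target_frames < 1:
            raise ValueError("target_frames must be >= 1")
        if self.sampling_mode not in ("uniform", "consecutive_k"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")


@dataclass
class TrainConfig:
    """Training protocol configuration."""

    split: Tuple[float, float, float] = (0.80, 0.10, 0.10)
    shift_augment_max: int = 10
    augment: bool = True
    batch_size: int = 16
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.split, list):
            self.split = tuple(self.split)
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0 <= self.shift_augment_max < 101 // 2:
            raise ValueError("shift_augment_max must lie in [0, 50)")


_SECTIONS = {
    "sim": SimParams,
    "pipeline": PipelineParams,
    "train": TrainConfig,
}


def load_config(path: str | Path) -> dict:
    """Read a YAML config file with flat ``sim:``/``pipeline:``/``train:`` sections.

    Missing sections fall back to defaults; unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for section, cls in _SECTIONS.items():
        values = raw.get(section, {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        out[section] = cls(**values)
    return out


def save_config(cfg: dict, path: str | Path) -> None:
    """Write the configuration dict produced by :func:`load_config` back to YAML."""
    raw = {}
    for section, obj in cfg.items():
        d = dataclasses.asdict(obj)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        raw[section] = d
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
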