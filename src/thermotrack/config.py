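"""Structured pipeline configuration with validation and hashing.

Every run records the SHA-256 hash of its fully-resolved configuration so
outputs can be traced to exact settings; two runs with different settings can
never share a hash. Unknown keys are rejected at load time. Temperatures in
config files are given in degrees Celsius and converted to kelvin internally.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .core import (
    DEFAULT_FRAME_INTERVAL,
    DEFAULT_MEDIUM_INDEX,
    DEFAULT_PIXEL_SIZE,
    DEFAULT_WAVELENGTH,
)


@dataclass
class OpticsConfig:
    pixel_size: float = DEFAULT_PIXEL_SIZE        # um/px
    frame_interval: float = DEFAULT_FRAME_INTERVAL  # s
    wavelength: float = DEFAULT_WAVELENGTH        # um
    medium_index: float = DEFAULT_MEDIUM_INDEX

    def __post_init__(self):
        if min(self.pixel_size, self.frame_interval, self.wavelength,
               self.medium_index) <= 0:
            raise ValueError("optics parameters must be positive")


@dataclass
class ReconConfig:
    enabled: bool = False        # False: input is already a projected 2D video
    z_min: float = -200.0        # um
    z_max: float = 200.0         # um
    z_step: float = 10.0         # um
    mode: str = "median"         # median | frame_to_frame | none


@dataclass
class DetectConfig:
    threshold: float | None = None   # None: 3 x robust sigma of subtracted video
    dbscan_eps: float = 3.0          # px
    dbscan_min_samples: int = 4
    subtraction_mode: str = "median"  # used when recon is skipped


@dataclass
class LinkConfig:
    max_link_distance: float = 10.0  # um per frame
    max_gap_frames: int = 2
    min_track_frames: int = 15


@dataclass
class ClassifyConfig:
    seed: int = 0
    n_trees: int = 200
    threshold: float = 0.5
    model_path: str | None = None    # load instead of training the default


@dataclass
class SummariesConfig:
    min_area: int = 4
    max_area: int | None = None
    volume_of_view_uL: float | None = None   # None: derived from field + depth
    chamber_depth_um: float = 1000.0
    cell_concentration_per_mL: float | None = None


@dataclass
class ViscosityConfig:
    A: float = 2.414e-5   # Pa*s
    B: float = 247.8      # K
    C: float = 140.0      # K
    base: float = 10.0


@dataclass
class PipelineConfig:
    """All settings for one pipeline run, nested by stage."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    link: LinkConfig = field(default_factory=LinkConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    summaries: SummariesConfig = field(default_factory=SummariesConfig)
    viscosity: ViscosityConfig = field(default_factory=ViscosityConfig)
    temperature_celsius: float | None = None

    @property
    def temperature_kelvin(self) -> float | None:
        if self.temperature_celsius is None:
            return None
        return self.temperature_celsius + 273.15

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """SHA-256 of the canonical JSON form of the resolved config."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in sections:
                raise ValueError(f"unknown config section or key: {key!r}")
            f = sections[key]
            is_section = (f.default_factory is not dataclasses.MISSING
                          and dataclasses.is_dataclass(f.default_factory()))
            if is_section:
                sub_cls = type(f.default_factory())
                valid = {sf.name for sf in dataclasses.fields(sub_cls)}
                unknown = set(value) - valid
                if unknown:
                    raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
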