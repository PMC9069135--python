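"""Core in-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: default object-space pixel pitch, micrometres per pixel
DEFAULT_PIXEL_SIZE = 0.178
#: default frame interval in seconds (15 frames per second)
DEFAULT_FRAME_INTERVAL = 1.0 / 15.0
#: default illumination wavelength in micrometres (520 nm laser)
DEFAULT_WAVELENGTH = 0.520
#: default refractive index of the aqueous medium
DEFAULT_MEDIUM_INDEX = 1.33


@dataclass
class VideoStack:
    """Ordered monochrome frames with the physical calibration every
    downstream unit conversion relies on.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity (real) or complex-amplitude frames. All frames share one shape.
    pixel_size : float
        Object-space pixel pitch in micrometres per pixel.
    frame_interval : float
        Time between consecutive frames in seconds (constant frame rate assumed).
    wavelength : float
        Illumination wavelength in micrometres.
    medium_index : float
        Refractive index of the immersion/sample medium.
    time_origin : float
        Time of the first frame in seconds. Frame-to-frame subtraction shifts
        this by one frame interval.
    """

    frames: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    wavelength: float = DEFAULT_WAVELENGTH
    medium_index: float = DEFAULT_MEDIUM_INDEX
    time_origin: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) array, got shape {self.frames.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Per-frame timestamps in seconds (index x frame_interval + origin)."""
        return self.time_origin + np.arange(self.n_frames) * self.frame_interval

    def with_frames(self, frames: np.ndarray, time_origin: float | None = None) -> "VideoStack":
        """Copy of the calibration wrapped around new frame data."""
        out = replace(self, frames=np.asarray(frames))
        if time_origin is not None:
            out.time_origin = time_origin
        return out


@dataclass
class Detection:
    """One detected object in one frame.

    Centroids are intensity-weighted and reported in object-space micrometres
    at pixel centres: x = column * pixel_size, y = row * pixel_size.
    """

    frame_index: int
    x: float
    y: float
    pixel_count: int
    intensity_sum: float = 0.0

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Track:
    """Time-ordered positions of one object; the unit of all track statistics.

    ``gap_flags[i]`` is True where the position was linearly interpolated
    across a detection gap rather than observed.
    """

    track_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    gap_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    frames: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.gap_flags is None:
            self.gap_flags = np.zeros(self.t.shape, dtype=bool)
        self.gap_flags = np.asarray(self.gap_flags, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.gap_flags) == n):
            raise ValueError("t, x, y, gap_flags must have equal length")
        if n < 2:
            raise ValueError("a track needs at least 2 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("track times must be strictly increasing")
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=int)

    @property
    def n_points(self) -> int:
        return len(self.t)

    @property
    def n_real_points(self) -> int:
        """Number of observed (non-interpolated) points."""
        return int(np.sum(~self.gap_flags))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) positions in micrometres."""
        return np.column_stack([self.x, self.y])
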