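"""Recording-level products: Motion History Images and motile fraction.

A Motion History Image (MHI) compresses a whole video into one picture by
mapping each pixel to the time index at which its intensity changed most —
moving objects leave time-coded traces that make motility patterns visible at
a glance. The motile fraction of a sample is the mean number of motile cells
per imaging volume divided by the total cell concentration; non-motile cells
need not be counted individually (they are often impossible to count once
cells cluster on surfaces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Track, VideoStack

#: instantaneous imaging volume of a 365 um x 365 um x 1 mm field, in uL
DEFAULT_VOLUME_OF_VIEW_UL = 0.365 * 0.365 * 1.0  # mm^3 == uL


def volume_of_view_uL(width_um: float, height_um: float, depth_um: float) -> float:
    """Imaging volume in microlitres (1 uL = 1e9 um^3)."""
    return width_um * height_um * depth_um / 1e9


@dataclass
class MotionHistoryImage:
    """Per-pixel time index (and magnitude) of the largest intensity change."""

    index_map: np.ndarray      # int frame index of largest change
    magnitude_map: np.ndarray  # that largest change, >= 0
    mask: np.ndarray           # True where max change >= threshold
    n_frames: int
    colormap: str = "viridis"

    def render(self):
        """Render to an RGBA array (masked pixels black)."""
        import matplotlib.colors as mcolors
        from matplotlib import colormaps

        norm = mcolors.Normalize(vmin=0, vmax=max(self.n_frames - 1, 1))
        rgba = colormaps[self.colormap](norm(self.index_map))
        rgba[~self.mask] = (0, 0, 0, 1)
        return rgba


def motion_history_image(stack: VideoStack, mode: str = "median",
                         threshold: float | None = None) -> MotionHistoryImage:
    """Compute the MHI of a video.

    mode='median': change series is |frame_t - temporal median|, index in
    [0, N-1]. mode='difference': |frame_{t+1} - frame_t|, index in [0, N-2].
    Ties break toward the earliest frame; pixels whose maximum change is below
    ``threshold`` (default: 3 x robust noise sigma) are masked.
    """
    if stack.n_frames < 2:
        raise ValueError("MHI needs at least 2 frames")
    frames = stack.frames.real
    if mode == "median":
        change = np.abs(frames - np.median(frames, axis=0))
    elif mode == "difference":
        change = np.abs(np.diff(frames, axis=0))
    else:
        raise ValueError(f"unknown MHI mode {mode!r}")
    if threshold is None:
        from .tracking import robust_change_threshold
        threshold = robust_change_threshold(change)
    index_map = np.argmax(change, axis=0)  # argmax returns the first maximum
    magnitude_map = np.max(change, axis=0)
    mask = magnitude_map >= threshold
    return MotionHistoryImage(index_map=index_map, magnitude_map=magnitude_map,
                              mask=mask, n_frames=change.shape[0])


_EIGHT_CONN = np.ones((3, 3), dtype=int)


def count_motile_per_frame(frames: np.ndarray, threshold: float,
                           min_area: int = 4,
                           max_area: int | None = None) -> np.ndarray:
    """Per-frame count of connected supra-threshold components in a size range.

    Intended for frame-to-frame subtracted video, where only moving cells
    leave signal. Components use 8-connectivity on |frame| > threshold and
    are counted when min_area <= area <= max_area (max_area=None: unbounded).
    """
    frames = np.asarray(frames)
    counts = np.zeros(frames.shape[0], dtype=int)
    for fi in range(frames.shape[0]):
        binary = np.abs(frames[fi]) > threshold
        labelled, n = ndimage.label(binary, structure=_EIGHT_CONN)
        if n == 0:
            continue
        areas = ndimage.sum_labels(binary, labelled, index=np.arange(1, n + 1))
        ok = areas >= min_area
        if max_area is not None:
            ok &= areas <= max_area
        counts[fi] = int(ok.sum())
    return counts


def count_motile_tracks_per_frame(tracks: list[Track], labels,
                                  n_frames: int) -> np.ndarray:
    """Per-frame count of motile-labelled tracks covering each frame.

    Uses the classifier's motile calls rather than raw blob counts; robust to
    track fragmentation as long as each swimmer is covered by some motile
    track in each frame.
    """
    counts = np.zeros(n_frames, dtype=int)
    for tr, lab in zip(tracks, labels):
        if getattr(lab, "label", lab) != "motile":
            continue
        if tr.frames is not None:
            idx = tr.frames
        else:
            idx = np.round(tr.t / np.median(np.diff(tr.t))).astype(int)
        idx = idx[(idx >= 0) & (idx < n_frames)]
        counts[idx] += 1
    return counts


@dataclass
class MotileFractionResult:
    """Motile-fraction estimate for one recording."""

    mean_motile_per_frame: float
    volume_of_view_uL: float
    cell_concentration_per_mL: float
    fraction: float


def motile_fraction(mean_count: float, volume_of_view_uL: float,
                    cell_concentration_per_mL: float) -> MotileFractionResult:
    """fraction = (mean motile count / volume in mL) / concentration.

    ``mean_count`` is the average number of motile cells per frame;
    the imaging volume is given in uL and the concentration in cells/mL.
    """
    if cell_concentration_per_mL <= 0:
        raise ValueError("cell concentration must be positive")
    if volume_of_view_uL <= 0:
        raise ValueError("volume of view must be positive")
    volume_mL = volume_of_view_uL * 1e-3
    fraction = (mean_count / volume_mL) / cell_concentration_per_mL
    return MotileFractionResult(
        mean_motile_per_frame=float(mean_count),
        volume_of_view_uL=float(volume_of_view_uL),
        cell_concentration_per_mL=float(cell_concentration_per_mL),
        fraction=float(fraction),
    )


def concentration_from_od(od: float, dilution: float,
                          cells_per_mL_per_od: float) -> float:
    """Cells/mL from optical density x dilution with a user calibration.

    No default calibration is shipped; the OD-to-count factor must come from
    an independent count (e.g. hemocytometer).
    """
    if cells_per_mL_per_od <= 0:
        raise ValueError("calibration factor must be positive")
    return od * dilution * cells_per_mL_per_od
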