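"""Numerical refocusing of hologram video into tracking-ready 2D projections.

A recorded hologram encodes the scattered field; propagating its angular
spectrum to a set of Z planes brings objects throughout the chamber depth into
focus one plane at a time. The pipeline here is: background subtraction
(temporal median, or frame-to-frame differencing when surface-adherent cells
make the median unusable), angular-spectrum propagation over a Z range, and a
per-pixel maximum projection over Z that collapses the refocused volume into a
2D video suitable for particle tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import VideoStack

SUBTRACTION_MODES = ("median", "frame_to_frame", "none")


@dataclass
class ReconstructionPlan:
    """Z sweep and background handling for one reconstruction run.

    z_min, z_max, z_step are propagation distances in micrometres relative to
    the recorded focal plane. A chamber-depth-scale sweep (total range of a few
    hundred micrometres, e.g. -200..+200 in 10 um steps) is typical.
    """

    z_min: float = 0.0
    z_max: float = 0.0
    z_step: float = 10.0
    subtraction_mode: str = "median"

    def __post_init__(self) -> None:
        if self.z_min > self.z_max:
            raise ValueError("z_min must not exceed z_max")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if self.subtraction_mode not in SUBTRACTION_MODES:
            raise ValueError(
                f"subtraction_mode must be one of {SUBTRACTION_MODES}, "
                f"got {self.subtraction_mode!r}"
            )

    @property
    def z_planes(self) -> np.ndarray:
        """Propagation distances, inclusive of both ends (um)."""
        n = int(round((self.z_max - self.z_min) / self.z_step)) + 1
        return self.z_min + self.z_step * np.arange(n)


def median_subtract(stack: VideoStack) -> VideoStack:
    """Subtract the per-pixel temporal median from every frame.

    Suppresses everything stationary (illumination structure, adherent cells,
    dust) while preserving moving objects. Needs at least 3 frames for the
    median to represent a background.
    """
    if stack.n_frames < 3:
        raise ValueError("median background subtraction needs at least 3 frames")
    background = np.median(stack.frames.real, axis=0)
    if np.iscomplexobj(stack.frames):
        background = background + 1j * np.median(stack.frames.imag, axis=0)
    return stack.with_frames(stack.frames - background)


def frame_to_frame_subtract(stack: VideoStack) -> VideoStack:
    """Consecutive-frame differences frame[i+1] - frame[i].

    Removes immobile objects even when they are present in every frame (where
    the median would fail only for objects absent in a majority of frames).
    The output has N-1 frames and its time origin advances by one interval.
    """
    if stack.n_frames < 2:
        raise ValueError("frame-to-frame subtraction needs at least 2 frames")
    diffs = np.diff(stack.frames, axis=0)
    return stack.with_frames(diffs, time_origin=stack.time_origin + stack.frame_interval)


def subtract_background(stack: VideoStack, mode: str) -> VideoStack:
    """Dispatch on subtraction mode ('median' | 'frame_to_frame' | 'none')."""
    if mode == "median":
        return median_subtract(stack)
    if mode == "frame_to_frame":
        return frame_to_frame_subtract(stack)
    if mode == "none":
        return stack
    raise ValueError(f"unknown subtraction mode {mode!r}")


def _complex_field(frame: np.ndarray) -> np.ndarray:
    """Lift a real frame to a complex field for propagation.

    Non-negative intensity frames become sqrt(I) with zero phase; signed
    (background-subtracted) frames keep their sign: sign(x) * sqrt(|x|).
    Complex frames pass through unchanged.
    """
    if np.iscomplexobj(frame):
        return frame
    return np.sign(frame) * np.sqrt(np.abs(frame)) + 0j


def angular_spectrum_propagate(field: np.ndarray, z: float, pixel_size: float,
                               wavelength: float, medium_index: float = 1.33) -> np.ndarray:
    """Propagate a 2D field a distance ``z`` (um) by the angular spectrum method.

    The field's 2D FFT is multiplied by the propagation kernel
    ``exp(i*2*pi*z*sqrt((n/lambda)^2 - fx^2 - fy^2))``; evanescent components
    (negative radicand) are zeroed, the standard band-limited choice. Lengths
    are all in micrometres. The kernel is unitary on the propagating band, so
    propagating +z then -z returns the original band-limited field.
    """
    field = np.asarray(field)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    f = _complex_field(field)
    if z == 0.0:
        # exact identity: avoid zeroing evanescent content that was never
        # asked to propagate anywhere
        return f.copy()
    ny, nx = f.shape
    fx = np.fft.fftfreq(nx, d=pixel_size)
    fy = np.fft.fftfreq(ny, d=pixel_size)
    fx2 = fx[np.newaxis, :] ** 2
    fy2 = fy[:, np.newaxis] ** 2
    radicand = (medium_index / wavelength) ** 2 - fx2 - fy2
    propagating = radicand >= 0.0
    kz = np.sqrt(np.where(propagating, radicand, 0.0))
    kernel = np.where(propagating, np.exp(2j * np.pi * z * kz), 0.0)
    spectrum = np.fft.fft2(f)
    return np.fft.ifft2(spectrum * kernel)


def reconstruct_volume(stack: VideoStack, plan: ReconstructionPlan) -> np.ndarray:
    """Amplitude reconstructions of every frame at every plane of the Z sweep.

    Applies the plan's background subtraction, then propagates each frame to
    each z in ``plan.z_planes`` and takes the modulus. Returns an array of
    shape (T, Z, H, W).
    """
    sub = subtract_background(stack, plan.subtraction_mode)
    zs = plan.z_planes
    out = np.empty((sub.n_frames, len(zs)) + sub.frame_shape, dtype=float)
    for ti in range(sub.n_frames):
        frame = sub.frames[ti]
        for zi, z in enumerate(zs):
            if z == 0.0:
                out[ti, zi] = np.abs(_complex_field(frame))
            else:
                out[ti, zi] = np.abs(
                    angular_spectrum_propagate(
                        frame, z, stack.pixel_size, stack.wavelength, stack.medium_index
                    )
                )
    return out


def max_z_projection(volume: np.ndarray, template: VideoStack | None = None,
                     time_origin: float | None = None) -> VideoStack | np.ndarray:
    """Per-frame, per-pixel maximum over Z planes of a (T, Z, H, W) volume.

    Returns a VideoStack when ``template`` supplies the calibration, otherwise
    the bare (T, H, W) array. This projection is the tracking input.
    """
    volume = np.asarray(volume)
    if volume.size == 0:
        raise ValueError("cannot project an empty volume")
    if volume.ndim != 4:
        raise ValueError(f"expected a (T, Z, H, W) volume, got shape {volume.shape}")
    proj = volume.max(axis=1)
    if template is None:
        return proj
    return template.with_frames(proj, time_origin=time_origin)


def reconstruct_and_project(stack: VideoStack, plan: ReconstructionPlan) -> VideoStack:
    """Convenience: subtraction + Z sweep + max projection in one call."""
    volume = reconstruct_volume(stack, plan)
    origin = stack.time_origin
    if plan.subtraction_mode == "frame_to_frame":
        origin += stack.frame_interval
    return max_z_projection(volume, template=stack, time_origin=origin)
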