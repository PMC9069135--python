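"""Per-track motility features and the covariance diffusion estimator.

Each track yields a fixed-order numeric feature vector: mean/max speed, mean
acceleration, net displacement and its rate, the dimensionless displacement
ratio D/(<v>*T) (1 for a straight run, ~0 for a closed loop), sinuosity
(path length over end-to-end displacement; 1 for a straight path), turning
angles, and autocorrelations of speed, velocity and turn angle at 1 s and 2 s
lags. These feed the motile/non-motile classifier and the swim-type rules.

The diffusion coefficient of passive (Brownian) tracks is estimated with the
covariance-based estimator, per axis

    D_hat = <dx_n^2> / (2*dt) + <dx_n * dx_{n+1}> / dt,

whose second term cancels the bias that static localization noise puts on the
naive mean-squared-step estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .core import Track

#: cap returned for sinuosity when end-to-end displacement is zero
SINUOSITY_CAP = 1e6

#: fixed feature order used by the classifier and the CSV export
FEATURE_NAMES = (
    "mean_speed",
    "max_speed",
    "mean_acceleration",
    "net_displacement",
    "displacement_rate",
    "displacement_ratio",
    "sinuosity",
    "mean_step_angle",
    "max_step_angle",
    "speed_autocorr_1s",
    "speed_autocorr_2s",
    "velocity_autocorr_1s",
    "velocity_autocorr_2s",
    "turn_angle_autocorr_1s",
    "turn_angle_autocorr_2s",
    "track_duration",
    "n_points",
)


@dataclass
class TrackFeatures:
    """Fixed-order feature vector for one track (units in field docstrings)."""

    mean_speed: float            # um/s
    max_speed: float             # um/s, maximum instantaneous step speed
    mean_acceleration: float     # um/s^2
    net_displacement: float      # um, ||last - first||
    displacement_rate: float     # um/s, net displacement / duration
    displacement_ratio: float    # dimensionless, net / (mean_speed * duration)
    sinuosity: float             # dimensionless >= 1, path / chord
    mean_step_angle: float       # rad
    max_step_angle: float        # rad
    speed_autocorr_1s: float
    speed_autocorr_2s: float
    velocity_autocorr_1s: float
    velocity_autocorr_2s: float
    turn_angle_autocorr_1s: float
    turn_angle_autocorr_2s: float
    track_duration: float        # s
    n_points: int
    sinuosity_capped: bool = False
    track_id: int | None = None

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return FEATURE_NAMES


def _dt(track: Track) -> float:
    return float(np.median(np.diff(track.t)))


def _steps(track: Track) -> np.ndarray:
    return np.diff(track.positions, axis=0)


def mean_speed(track: Track) -> float:
    """Mean speed over the N-1 steps of an N-point track, um/s.

    Average step length divided by the frame interval; a constant-velocity
    track returns exactly its speed.
    """
    if track.n_points < 2:
        raise ValueError("mean speed needs at least 2 points")
    dt = _dt(track)
    step_lengths = np.linalg.norm(_steps(track), axis=1)
    return float(step_lengths.mean() / dt)


def max_speed(track: Track) -> float:
    """Maximum instantaneous (per-step) speed, um/s."""
    if track.n_points < 2:
        raise ValueError("max speed needs at least 2 points")
    dt = _dt(track)
    return float(np.linalg.norm(_steps(track), axis=1).max() / dt)


def mean_acceleration(track: Track) -> float:
    """Mean magnitude of inter-frame velocity change over dt, um/s^2."""
    if track.n_points < 3:
        raise ValueError("mean acceleration needs at least 3 points")
    dt = _dt(track)
    velocities = _steps(track) / dt
    dv = np.diff(velocities, axis=0)
    return float(np.linalg.norm(dv, axis=1).mean() / dt)


def net_displacement(track: Track) -> tuple[float, float, float]:
    """(displacement um, displacement rate um/s, displacement ratio).

    displacement = ||last - first||; rate = displacement / duration;
    ratio = displacement / (mean_speed * duration), i.e. chord over path,
    which is 1 for straight monotone motion and ~0 for a closed loop.
    """
    if track.n_points < 2:
        raise ValueError("net displacement needs at least 2 points")
    duration = track.duration
    if duration <= 0:
        raise ValueError("track duration must be positive")
    disp = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    rate = disp / duration
    path = mean_speed(track) * duration
    ratio = disp / path if path > 0 else 0.0
    return disp, rate, ratio


def sinuosity(track: Track) -> tuple[float, bool]:
    """Path length over end-to-end displacement (>= 1); (value, capped flag).

    Movement-inefficiency measure: 1 for a straight path, ~pi/2 for a
    semicircle, large for circling; a zero chord returns the configured cap
    with the flag set. Values above ~20 indicate circular tracks.
    """
    if track.n_points < 2:
        raise ValueError("sinuosity needs at least 2 points")
    path = float(np.linalg.norm(_steps(track), axis=1).sum())
    chord = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    if chord == 0.0:
        return SINUOSITY_CAP, True
    return max(path / chord, 1.0), False


def step_angles(track: Track) -> np.ndarray:
    """Turning angle between consecutive displacement vectors, rad in [0, pi].

    Zero-length steps are skipped (they carry no direction).
    """
    if track.n_points < 3:
        raise ValueError("step angles need at least 3 points")
    steps = _steps(track)
    lengths = np.linalg.norm(steps, axis=1)
    angles = []
    prev = None
    for vec, ln in zip(steps, lengths):
        if ln == 0:
            continue
        if prev is not None:
            cosang = np.dot(prev, vec) / (np.linalg.norm(prev) * ln)
            angles.append(math.acos(min(1.0, max(-1.0, cosang))))
        prev = vec
    return np.asarray(angles)


def track_autocorrelation(series: np.ndarray, lag_seconds: float, dt: float) -> float:
    """Pearson autocorrelation of a scalar series at the given time lag.

    The lag in frames is round(lag_seconds / dt). Returns NaN (a missing-value
    marker, not an exception) when the series is too short or constant.
    """
    series = np.asarray(series, dtype=float)
    lag = int(round(lag_seconds / dt))
    if lag < 1 or lag >= len(series) - 1:
        return float("nan")
    a, b = series[:-lag], series[lag:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def velocity_autocorrelation(track: Track, lag_seconds: float) -> float:
    """Normalized mean dot-product velocity autocorrelation at a time lag.

    <v_t . v_{t+lag}> / <||v||^2>; NaN when the track is too short.
    """
    dt = _dt(track)
    velocities = _steps(track) / dt
    lag = int(round(lag_seconds / dt))
    if lag < 1 or lag >= len(velocities) - 1:
        return float("nan")
    denom = np.mean(np.sum(velocities ** 2, axis=1))
    if denom == 0:
        return float("nan")
    num = np.mean(np.sum(velocities[:-lag] * velocities[lag:], axis=1))
    return float(num / denom)


def feature_vector(track: Track) -> TrackFeatures:
    """Assemble the full TrackFeatures vector for one track.

    Deterministic for identical input; members that are undefined for a short
    track become NaN markers rather than raising.
    """
    dt = _dt(track)
    v_mean = mean_speed(track)
    v_max = max_speed(track)
    accel = mean_acceleration(track) if track.n_points >= 3 else float("nan")
    disp, rate, ratio = net_displacement(track)
    sin, capped = sinuosity(track)
    if track.n_points >= 3:
        angles = step_angles(track)
        ang_mean = float(angles.mean()) if angles.size else float("nan")
        ang_max = float(angles.max()) if angles.size else float("nan")
    else:
        angles = np.array([])
        ang_mean = ang_max = float("nan")
    speeds = np.linalg.norm(_steps(track), axis=1) / dt
    return TrackFeatures(
        mean_speed=v_mean,
        max_speed=v_max,
        mean_acceleration=accel,
        net_displacement=disp,
        displacement_rate=rate,
        displacement_ratio=ratio,
        sinuosity=sin,
        mean_step_angle=ang_mean,
        max_step_angle=ang_max,
        speed_autocorr_1s=track_autocorrelation(speeds, 1.0, dt),
        speed_autocorr_2s=track_autocorrelation(speeds, 2.0, dt),
        velocity_autocorr_1s=velocity_autocorrelation(track, 1.0),
        velocity_autocorr_2s=velocity_autocorrelation(track, 2.0),
        turn_angle_autocorr_1s=track_autocorrelation(angles, 1.0, dt),
        turn_angle_autocorr_2s=track_autocorrelation(angles, 2.0, dt),
        track_duration=track.duration,
        n_points=track.n_points,
        sinuosity_capped=capped,
        track_id=track.track_id,
    )


def feature_matrix(feature_list: list[TrackFeatures]) -> np.ndarray:
    """(n_tracks, n_features) array in FEATURE_NAMES order."""
    return np.vstack([f.to_array() for f in feature_list])


def feature_correlation_matrix(feature_list: list[TrackFeatures]) -> np.ndarray:
    """Pairwise Pearson correlations between features over tracks.

    Missing values are pairwise-deleted; entries involving a constant column
    are NaN. Diagonal is 1 wherever defined. Needs at least 3 tracks.
    """
    if len(feature_list) < 3:
        raise ValueError("correlation matrix needs at least 3 tracks")
    X = feature_matrix(feature_list)
    p = X.shape[1]
    out = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(i, p):
            mask = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            if mask.sum() < 3:
                continue
            a, b = X[mask, i], X[mask, j]
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            out[i, j] = out[j, i] = r
    return out


@dataclass
class DiffusionEstimate:
    """Covariance-based diffusion estimate for one track."""

    D_hat: float                 # um^2/s, mean of the two axis estimates
    n_steps: int
    per_axis: tuple[float, float]


def covariance_diffusion(track: Track, min_steps: int = 5) -> DiffusionEstimate:
    """Covariance diffusion estimator, robust to static localization noise.

    Per axis D = <dx^2>/(2*dt) + <dx_n dx_{n+1}>/dt; the adjacent-step
    covariance term removes the positive bias localization noise adds to the
    squared-step term. Requires at least ``min_steps`` displacement steps.
    """
    steps = _steps(track)
    n_steps = len(steps)
    if n_steps < max(min_steps, 2):
        raise ValueError(
            f"track has {n_steps} steps; covariance estimator needs >= {max(min_steps, 2)}"
        )
    dt = _dt(track)
    per_axis = []
    for axis in range(2):
        dx = steps[:, axis]
        d = np.mean(dx ** 2) / (2 * dt) + np.mean(dx[:-1] * dx[1:]) / dt
        per_axis.append(float(d))
    return DiffusionEstimate(
        D_hat=float(np.mean(per_axis)), n_steps=n_steps,
        per_axis=(per_axis[0], per_axis[1]),
    )


@dataclass
class DiffusionSummary:
    """Sample-level aggregation of per-track diffusion estimates."""

    mean_D: float
    sd_D: float
    n_tracks: int
    flagged: bool   # True when fewer tracks were accepted than required


def sample_diffusion(tracks: list[Track], min_steps: int = 5,
                     min_tracks: int = 10) -> DiffusionSummary:
    """Aggregate covariance-D estimates over tracks; mean +- SD.

    A recording should contribute at least ``min_tracks`` accepted tracks for
    a trustworthy estimate; fewer tracks produce a flagged (not rejected)
    summary.
    """
    estimates = []
    for tr in tracks:
        try:
            estimates.append(covariance_diffusion(tr, min_steps=min_steps).D_hat)
        except ValueError:
            continue
    if not estimates:
        return DiffusionSummary(float("nan"), float("nan"), 0, True)
    arr = np.asarray(estimates)
    return DiffusionSummary(
        mean_D=float(arr.mean()),
        sd_D=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n_tracks=len(arr),
        flagged=len(arr) < min_tracks,
    )
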