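"""Detection and linking: clusters of pixel change become particle tracks.

Moving objects are found as pixels whose absolute change from the background
exceeds a threshold, grouped into detections with DBSCAN, and linked frame to
frame by solving a linear assignment problem (LAP) with birth/death dummy
nodes, Jaqaman-style: linking costs are squared centroid distances capped at a
maximum per-frame link distance, and the alternative (start/terminate a track)
costs the squared cap. A second assignment pass closes short detection gaps,
filling the missing positions by linear interpolation and flagging them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from .core import Detection, Track, VideoStack

_FORBIDDEN = 1e15  # large finite cost standing in for an impossible assignment


@dataclass
class LinkerConfig:
    """Detection and linking parameters.

    max_link_distance is in um per frame and covers the fastest plausible
    per-frame displacement (10 um/frame accommodates instantaneous speeds of
    150 um/s at 15 fps). change_threshold=None selects the automatic
    3 x robust-sigma rule (median absolute deviation x 1.4826) computed on the
    background-subtracted video. Tracks shorter than min_track_frames observed
    points are discarded downstream.
    """

    max_link_distance: float = 10.0
    max_gap_frames: int = 2
    min_track_frames: int = 15
    change_threshold: float | None = None
    dbscan_eps: float = 3.0
    dbscan_min_samples: int = 4

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be positive")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be non-negative")
        if self.min_track_frames < 2:
            raise ValueError("min_track_frames must be at least 2")
        if self.change_threshold is not None and self.change_threshold <= 0:
            raise ValueError("change_threshold must be positive")
        if self.dbscan_eps <= 0 or self.dbscan_min_samples < 1:
            raise ValueError("invalid DBSCAN parameters")


def robust_change_threshold(frames: np.ndarray, n_sigma: float = 3.0) -> float:
    """n_sigma x robust noise sigma (MAD x 1.4826) of a subtracted video."""
    data = np.abs(np.asarray(frames)).ravel()
    med = np.median(data)
    mad = np.median(np.abs(data - med))
    sigma = 1.4826 * mad
    if sigma == 0.0:
        sigma = float(np.std(data)) or 1e-12
    return float(med + n_sigma * sigma)


def detect_changes(frame: np.ndarray, background: np.ndarray, threshold: float) -> np.ndarray:
    """Pixel coordinates (row, col) where |frame - background| > threshold."""
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rows, cols = np.nonzero(np.abs(frame - background) > threshold)
    return np.column_stack([rows, cols])


def cluster_changes(changed_pixels: np.ndarray, eps: float, min_samples: int,
                    pixel_size: float, frame_index: int = 0,
                    weights: np.ndarray | None = None) -> list[Detection]:
    """DBSCAN over changed pixel coordinates; each cluster becomes a Detection.

    Clustering runs in pixel units with Euclidean eps; noise points are
    discarded. Centroids are weighted by ``weights`` (typically the absolute
    change magnitude per pixel) when given, and converted to micrometres with
    x = column * pixel_size, y = row * pixel_size.
    """
    changed_pixels = np.asarray(changed_pixels)
    if changed_pixels.size == 0:
        return []
    if eps <= 0 or min_samples < 1:
        raise ValueError("invalid DBSCAN parameters")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(changed_pixels)
    if weights is None:
        weights = np.ones(len(changed_pixels))
    weights = np.asarray(weights, dtype=float)
    detections = []
    for lab in sorted(set(labels) - {-1}):
        mask = labels == lab
        pts = changed_pixels[mask].astype(float)
        w = weights[mask]
        wsum = w.sum()
        if wsum <= 0:
            w = np.ones(len(pts))
            wsum = w.sum()
        centroid = (pts * w[:, None]).sum(axis=0) / wsum  # (row, col)
        detections.append(
            Detection(
                frame_index=frame_index,
                x=float(centroid[1] * pixel_size),
                y=float(centroid[0] * pixel_size),
                pixel_count=int(mask.sum()),
                intensity_sum=float(wsum),
            )
        )
    return detections


def detect_video(stack: VideoStack, cfg: LinkerConfig,
                 background: np.ndarray | None = None) -> list[list[Detection]]:
    """Run change detection + clustering on every frame of a subtracted video.

    ``background`` defaults to zero (the video is assumed already background-
    subtracted). Returns one detection list per frame.
    """
    threshold = cfg.change_threshold
    if threshold is None:
        threshold = robust_change_threshold(stack.frames)
    if background is None:
        background = np.zeros(stack.frame_shape)
    per_frame: list[list[Detection]] = []
    for fi in range(stack.n_frames):
        change = np.abs(stack.frames[fi] - background)
        pixels = detect_changes(stack.frames[fi], background, threshold)
        weights = change[pixels[:, 0], pixels[:, 1]] if pixels.size else None
        per_frame.append(
            cluster_changes(pixels, cfg.dbscan_eps, cfg.dbscan_min_samples,
                            stack.pixel_size, frame_index=fi, weights=weights)
        )
    return per_frame


def _solve_frame_lap(src_xy: np.ndarray, dst_xy: np.ndarray,
                     max_dist: float) -> list[tuple[int, int]]:
    """Jaqaman-style frame-to-frame assignment.

    Square cost matrix of size (n+m): top-left squared distances (capped at
    max_dist), top-right/bottom-left diagonal birth/death alternatives at
    max_dist**2, bottom-right zeros. Returns accepted (source, target) links.
    """
    n, m = len(src_xy), len(dst_xy)
    if n == 0 or m == 0:
        return []
    b = max_dist ** 2
    cost = np.full((n + m, m + n), _FORBIDDEN)
    d = cdist(src_xy, dst_xy)
    link = np.where(d <= max_dist, d ** 2, _FORBIDDEN)
    cost[:n, :m] = link
    cost[:n, m:] = np.where(np.eye(n, dtype=bool), b, _FORBIDDEN)
    cost[n:, :m] = np.where(np.eye(m, dtype=bool), b, _FORBIDDEN)
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if i < n and j < m and link[i, j] < _FORBIDDEN]


class _Segment:
    __slots__ = ("detections",)

    def __init__(self, det: Detection):
        self.detections = [det]

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame_index


def _group_by_frame(detections) -> dict[int, list[Detection]]:
    if isinstance(detections, dict):
        return {int(k): list(v) for k, v in detections.items()}
    if len(detections) and isinstance(detections[0], Detection):
        grouped: dict[int, list[Detection]] = {}
        for det in detections:
            grouped.setdefault(det.frame_index, []).append(det)
        return grouped
    return {i: list(frame) for i, frame in enumerate(detections)}


def link_tracks(detections, cfg: LinkerConfig, frame_interval: float = 1.0 / 15.0,
                time_origin: float = 0.0, n_frames: int | None = None) -> list[Track]:
    """Link per-frame detections into tracks (frame LAP + gap closing).

    ``detections`` may be a list of per-frame detection lists (index = frame),
    a flat list of Detection, or a {frame_index: [Detection]} mapping. Frames
    must form a contiguous range; a frame with no detections must be present
    as an empty list (or covered by ``n_frames``), otherwise the indexing is
    ambiguous and a ValueError is raised.
    """
    grouped = _group_by_frame(detections)
    if not grouped:
        return []
    f_lo, f_hi = min(grouped), max(grouped)
    if n_frames is not None:
        if f_lo < 0 or f_hi >= n_frames:
            raise ValueError("detection frame indices outside the stated frame range")
        f_lo, f_hi = 0, n_frames - 1
    elif isinstance(detections, (list, tuple)) and len(detections) and (
            not isinstance(detections[0], Detection)):
        pass  # per-frame lists are contiguous by construction
    elif set(grouped) != set(range(f_lo, f_hi + 1)):
        raise ValueError(
            "non-contiguous frame indices; pass per-frame lists (empty for "
            "frames without detections) or n_frames to declare the range"
        )
    frames = [grouped.get(fi, []) for fi in range(f_lo, f_hi + 1)]

    # --- pass 1: frame-to-frame linking into segments ---
    open_segments: list[_Segment] = []   # segments ending at the previous frame
    closed_segments: list[_Segment] = []
    for fi, dets in enumerate(frames):
        if fi == 0:
            open_segments = [_Segment(d) for d in dets]
            continue
        src_xy = np.array([s.detections[-1].xy for s in open_segments]).reshape(-1, 2)
        dst_xy = np.array([d.xy for d in dets]).reshape(-1, 2)
        links = _solve_frame_lap(src_xy, dst_xy, cfg.max_link_distance)
        linked_src = {i for i, _ in links}
        linked_dst = {j for _, j in links}
        next_open: list[_Segment] = []
        for i, j in sorted(links):
            open_segments[i].detections.append(dets[j])
            next_open.append(open_segments[i])
        for i, seg in enumerate(open_segments):
            if i not in linked_src:
                closed_segments.append(seg)
        for j, det in enumerate(dets):
            if j not in linked_dst:
                next_open.append(_Segment(det))
        open_segments = next_open
    closed_segments.extend(open_segments)
    segments = [s for s in closed_segments if len(s.detections) >= 1]

    # --- pass 2: gap closing between segment ends and segment starts ---
    if cfg.max_gap_frames > 0 and len(segments) > 1:
        segments = _close_gaps(segments, cfg)

    # --- build Track objects, interpolating gap-closed frames ---
    tracks: list[Track] = []
    tid = 0
    for seg in segments:
        if len(seg.detections) < 2:
            continue
        fr, xs, ys, gaps = [], [], [], []
        prev = None
        for det in seg.detections:
            if prev is not None and det.frame_index > prev.frame_index + 1:
                span = det.frame_index - prev.frame_index
                for k in range(1, span):
                    frac = k / span
                    fr.append(prev.frame_index + k)
                    xs.append(prev.x + frac * (det.x - prev.x))
                    ys.append(prev.y + frac * (det.y - prev.y))
                    gaps.append(True)
            fr.append(det.frame_index)
            xs.append(det.x)
            ys.append(det.y)
            gaps.append(False)
            prev = det
        t = time_origin + np.asarray(fr) * frame_interval
        tracks.append(Track(track_id=tid, t=t, x=xs, y=ys,
                            gap_flags=gaps, frames=np.asarray(fr)))
        tid += 1
    return tracks


def _close_gaps(segments: list[_Segment], cfg: LinkerConfig) -> list[_Segment]:
    """Assignment between segment ends and later segment starts within the
    configured frame-gap and distance budget; merged chains are concatenated."""
    n = len(segments)
    cost = np.full((2 * n, 2 * n), _FORBIDDEN)
    b = (cfg.max_link_distance * (cfg.max_gap_frames + 1)) ** 2
    feasible = False
    for i, si in enumerate(segments):
        for j, sj in enumerate(segments):
            if i == j:
                continue
            span = sj.start_frame - si.end_frame
            if 2 <= span <= cfg.max_gap_frames + 1:
                d = np.linalg.norm(si.detections[-1].xy - sj.detections[0].xy)
                if d <= cfg.max_link_distance * span:
                    cost[i, j] = d ** 2
                    feasible = True
    if not feasible:
        return segments
    cost[:n, n:] = np.where(np.eye(n, dtype=bool), b, _FORBIDDEN)
    cost[n:, :n] = np.where(np.eye(n, dtype=bool), b, _FORBIDDEN)
    cost[n:, n:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    succ: dict[int, int] = {}
    for i, j in zip(rows, cols):
        if i < n and j < n and cost[i, j] < _FORBIDDEN:
            succ[i] = j
    has_pred = set(succ.values())
    merged: list[_Segment] = []
    for i in range(n):
        if i in has_pred:
            continue
        seg = segments[i]
        j = i
        while j in succ:
            j = succ[j]
            seg.detections.extend(segments[j].detections)
        merged.append(seg)
    return merged


def filter_tracks(tracks: list[Track], min_track_frames: int = 15) -> list[Track]:
    """Keep tracks with at least ``min_track_frames`` observed (non-gap) points.

    Short tracks carry too little information for motility statistics and are
    excluded from all downstream analysis.
    """
    return [tr for tr in tracks if tr.n_real_points >= min_track_frames]
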