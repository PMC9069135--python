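"""End-to-end orchestration: video in, tracks/features/labels/MHI out.

Stages: (optional) hologram reconstruction and Z projection -> background
subtraction -> change detection + clustering -> LAP linking -> short-track
exclusion -> feature extraction -> motile/non-motile classification ->
Motion History Image and motile-fraction summary. A RunManifest records the
config hash and per-stage counts for every run.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as classify_mod
from . import reconstruction, summaries, tracking
from .config import PipelineConfig
from .core import Track, VideoStack
from .features import TrackFeatures, feature_vector
from .io import features_to_dataframe, read_stack

logger = logging.getLogger("thermotrack")


@dataclass
class RunManifest:
    """Provenance and per-stage counts for one pipeline run."""

    input_path: str | None
    config_hash: str
    software_version: str
    seed: int
    n_frames: int
    n_detections: int
    n_tracks_linked: int
    n_tracks_kept: int
    n_tracks_excluded: int
    stage_seconds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_tracks_kept + self.n_tracks_excluded != self.n_tracks_linked:
            raise ValueError("track counts inconsistent: kept + excluded != linked")


@dataclass
class PipelineResult:
    """Everything one run produces."""

    video: VideoStack                 # the tracking input (subtracted/projected)
    detections: list
    tracks: list[Track]               # after short-track exclusion
    features: list[TrackFeatures]
    labels: list
    feature_table: pd.DataFrame
    mhi: summaries.MotionHistoryImage | None
    motile_fraction: summaries.MotileFractionResult | None
    manifest: RunManifest


def check_constant_frame_rate(timestamps, rel_tol: float = 1e-3) -> float:
    """Validate uniform frame timing; returns the frame interval.

    The tracker assumes (and checks for) a constant frame rate: dropped or
    unevenly timed frames would corrupt every per-frame statistic, so
    violations abort with a clear message.
    """
    ts = np.asarray(timestamps, dtype=float)
    if len(ts) < 2:
        raise ValueError("need at least 2 timestamps")
    intervals = np.diff(ts)
    dt = float(np.median(intervals))
    if dt <= 0 or np.any(np.abs(intervals - dt) > rel_tol * dt):
        raise ValueError(
            "non-constant frame rate detected; the pipeline requires uniform "
            "frame timing (ensure the acquisition did not drop frames)")
    return dt


def run_pipeline(video, config: PipelineConfig | None = None,
                 classifier: classify_mod.ClassifierModel | None = None,
                 timestamps=None, input_path: str | None = None) -> PipelineResult:
    """Run the full pipeline on a VideoStack or a readable path.

    ``video`` may be raw holograms (set config.recon.enabled) or projected
    2D intensity video. A classifier may be supplied; otherwise the default
    synthetic-trained model (config.classify.seed) is used, or loaded from
    config.classify.model_path when set.
    """
    config = config or PipelineConfig()
    t_start = time.time()
    stage_seconds: dict[str, float] = {}

    if not isinstance(video, VideoStack):
        input_path = str(video)
        video = read_stack(video, pixel_size=config.optics.pixel_size,
                           frame_interval=config.optics.frame_interval,
                           wavelength=config.optics.wavelength,
                           medium_index=config.optics.medium_index)
    if timestamps is not None:
        dt = check_constant_frame_rate(timestamps)
        video.frame_interval = dt
        video.time_origin = float(np.asarray(timestamps)[0])

    # --- reconstruction (optional) + background subtraction ---
    t0 = time.time()
    if config.recon.enabled:
        plan = reconstruction.ReconstructionPlan(
            z_min=config.recon.z_min, z_max=config.recon.z_max,
            z_step=config.recon.z_step, subtraction_mode=config.recon.mode)
        work = reconstruction.reconstruct_and_project(video, plan)
    else:
        work = reconstruction.subtract_background(video, config.detect.subtraction_mode)
    stage_seconds["reconstruct"] = time.time() - t0
    logger.info("reconstruct: %d frames in %.2fs", work.n_frames,
                stage_seconds["reconstruct"])

    # --- detection ---
    t0 = time.time()
    linker_cfg = tracking.LinkerConfig(
        max_link_distance=config.link.max_link_distance,
        max_gap_frames=config.link.max_gap_frames,
        min_track_frames=config.link.min_track_frames,
        change_threshold=config.detect.threshold,
        dbscan_eps=config.detect.dbscan_eps,
        dbscan_min_samples=config.detect.dbscan_min_samples)
    per_frame = tracking.detect_video(work, linker_cfg)
    n_detections = sum(len(d) for d in per_frame)
    stage_seconds["detect"] = time.time() - t0
    logger.info("detect: %d detections in %.2fs", n_detections, stage_seconds["detect"])
    if n_detections == 0:
        logger.warning("no detections; producing empty outputs")

    # --- linking + exclusion ---
    t0 = time.time()
    all_tracks = tracking.link_tracks(per_frame, linker_cfg,
                                      frame_interval=work.frame_interval,
                                      time_origin=work.time_origin)
    kept = tracking.filter_tracks(all_tracks, config.link.min_track_frames)
    stage_seconds["link"] = time.time() - t0
    logger.info("link: %d tracks, %d kept (>= %d frames) in %.2fs",
                len(all_tracks), len(kept), config.link.min_track_frames,
                stage_seconds["link"])

    # --- features ---
    t0 = time.time()
    feats = [feature_vector(tr) for tr in kept]
    stage_seconds["features"] = time.time() - t0

    # --- classification ---
    t0 = time.time()
    if classifier is None:
        if config.classify.model_path:
            classifier = classify_mod.ClassifierModel.load(config.classify.model_path)
        else:
            classifier = classify_mod.default_classifier(config.classify.seed)
    labels = classify_mod.classify_tracks(classifier, feats, tracks=kept,
                                          threshold=config.classify.threshold)
    stage_seconds["classify"] = time.time() - t0
    n_motile = sum(lab.label == "motile" for lab in labels)
    logger.info("classify: %d/%d motile in %.2fs", n_motile, len(labels),
                stage_seconds["classify"])

    # --- summaries ---
    t0 = time.time()
    mhi = summaries.motion_history_image(work) if work.n_frames >= 2 else None
    fraction = None
    vol = config.summaries.volume_of_view_uL
    if vol is None:
        h_um = work.frame_shape[0] * work.pixel_size
        w_um = work.frame_shape[1] * work.pixel_size
        vol = summaries.volume_of_view_uL(w_um, h_um, config.summaries.chamber_depth_um)
    conc = config.summaries.cell_concentration_per_mL
    if conc is not None:
        counts = summaries.count_motile_tracks_per_frame(kept, labels, work.n_frames)
        fraction = summaries.motile_fraction(counts.mean(), vol, conc)
    stage_seconds["summaries"] = time.time() - t0
    stage_seconds["total"] = time.time() - t_start

    from . import __version__
    manifest = RunManifest(
        input_path=input_path,
        config_hash=config.hash(),
        software_version=__version__,
        seed=config.classify.seed,
        n_frames=work.n_frames,
        n_detections=n_detections,
        n_tracks_linked=len(all_tracks),
        n_tracks_kept=len(kept),
        n_tracks_excluded=len(all_tracks) - len(kept),
        stage_seconds=stage_seconds,
    )
    return PipelineResult(
        video=work, detections=per_frame, tracks=kept, features=feats,
        labels=labels, feature_table=features_to_dataframe(feats, labels),
        mhi=mhi, motile_fraction=fraction, manifest=manifest,
    )
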