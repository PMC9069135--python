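"""Readers and writers: TIFF stacks, track JSON, feature CSV.

Tracks are exported as schema-versioned JSON so they can be imported into
other analysis packages losslessly (full float precision for t/x/y and the
per-point interpolation flags).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Track, VideoStack
from .features import FEATURE_NAMES, TrackFeatures

TRACKS_SCHEMA_VERSION = 1

_FRAME_SUFFIXES = (".tif", ".tiff", ".png")


def read_stack(path, pixel_size: float | None = None,
               frame_interval: float | None = None,
               wavelength: float | None = None,
               medium_index: float | None = None) -> VideoStack:
    """Read a multi-page TIFF or a directory of numbered frames into a VideoStack.

    Frames in a directory are taken in lexicographic filename order (use
    zero-padded numbering). Integer bit depths are converted to float; all
    frames must share one shape. Calibration keywords override the defaults.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise ValueError(f"no frame files found in {path}")
        frames = []
        for f in files:
            if f.suffix.lower() in (".tif", ".tiff"):
                frames.append(tifffile.imread(f))
            else:
                import imageio.v3 as iio
                frames.append(np.asarray(iio.imread(f)))
        shapes = {fr.shape for fr in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame shapes in {path}: {shapes}")
        arr = np.stack(frames)
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"expected (T, H, W) data, got shape {arr.shape}")
    if not np.iscomplexobj(arr):
        arr = arr.astype(float)
    kwargs = {}
    if pixel_size is not None:
        kwargs["pixel_size"] = pixel_size
    if frame_interval is not None:
        kwargs["frame_interval"] = frame_interval
    if wavelength is not None:
        kwargs["wavelength"] = wavelength
    if medium_index is not None:
        kwargs["medium_index"] = medium_index
    return VideoStack(arr, **kwargs)


def write_stack(path, stack: VideoStack) -> None:
    """Write a VideoStack as a multi-page float32 TIFF."""
    tifffile.imwrite(path, stack.frames.real.astype(np.float32))


def write_tracks_json(path, tracks: list[Track], provenance: dict | None = None) -> None:
    """Export tracks as schema-versioned JSON (t in s, x/y in um, gap flags)."""
    doc = {
        "schema_version": TRACKS_SCHEMA_VERSION,
        "provenance": provenance or {},
        "tracks": [
            {
                "track_id": int(tr.track_id),
                "points": [[float(t), float(x), float(y)]
                           for t, x, y in zip(tr.t, tr.x, tr.y)],
                "gap_flags": [bool(g) for g in tr.gap_flags],
                "frames": ([int(f) for f in tr.frames]
                           if tr.frames is not None else None),
            }
            for tr in tracks
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_tracks_json(path) -> list[Track]:
    """Read tracks back from JSON; raises on schema version mismatch."""
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != TRACKS_SCHEMA_VERSION:
        raise ValueError(
            f"tracks schema version {version!r} not supported "
            f"(expected {TRACKS_SCHEMA_VERSION})")
    tracks = []
    for entry in doc["tracks"]:
        pts = np.asarray(entry["points"], dtype=float)
        frames = entry.get("frames")
        tracks.append(Track(
            track_id=entry["track_id"],
            t=pts[:, 0], x=pts[:, 1], y=pts[:, 2],
            gap_flags=np.asarray(entry["gap_flags"], dtype=bool),
            frames=np.asarray(frames, dtype=int) if frames is not None else None,
        ))
    return tracks


def features_to_dataframe(feature_list: list[TrackFeatures],
                          labels=None) -> pd.DataFrame:
    """One row per track in fixed column order; units in the column comments.

    Speeds um/s, acceleration um/s^2, displacement um, duration s, angles rad.
    """
    rows = []
    for i, f in enumerate(feature_list):
        row = {"track_id": f.track_id if f.track_id is not None else i}
        row.update({name: getattr(f, name) for name in FEATURE_NAMES})
        row["sinuosity_capped"] = f.sinuosity_capped
        if labels is not None:
            lab = labels[i]
            row["label"] = lab.label
            row["motile_probability"] = lab.probability
            row["swim_type"] = lab.swim_type
        rows.append(row)
    return pd.DataFrame(rows)


def write_features_csv(path, feature_list: list[TrackFeatures], labels=None) -> None:
    features_to_dataframe(feature_list, labels).to_csv(path, index=False)
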