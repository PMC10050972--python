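"""Reading and writing the pipeline's on-disk formats.

Pose tracks and intensity traces travel as headered comma-separated-values
tables (the tracker-quantifier's native output format); synced series and
fit results are written as CSV and JSON respectively, rendered frames as
8-bit PNG.  Readers tolerate extra columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .records import IntensityTrace, PoseTrack, SyncedSeries

__all__ = [
    "write_pose_csv",
    "read_pose_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_synced_csv",
    "read_synced_csv",
    "write_frame_png",
    "write_json",
]

_POSE_COLS = ["t_s", "x_mm", "y_mm", "z_mm", "angle_deg"]
_TRACE_COLS = ["t_s", "roi_id", "intensity_gu"]


def _infer_fps(t: np.ndarray) -> float:
    if t.size < 2:
        raise ValueError("cannot infer fps from fewer than 2 samples")
    return 1.0 / float(np.median(np.diff(t)))


def write_pose_csv(track: PoseTrack, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    track.to_frame().to_csv(path, index=False, float_format="%.6f")
    return path


def read_pose_csv(path: str | Path, fps: float | None = None) -> PoseTrack:
    df = pd.read_csv(path)
    missing = set(_POSE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"pose file {path} missing columns {sorted(missing)}")
    t = df["t_s"].to_numpy(dtype=float)
    return PoseTrack(
        t=t,
        x=df["x_mm"].to_numpy(dtype=float),
        y=df["y_mm"].to_numpy(dtype=float),
        z=df["z_mm"].to_numpy(dtype=float),
        angle=df["angle_deg"].to_numpy(dtype=float),
        fps=fps if fps is not None else _infer_fps(t),
    )


def write_traces_csv(traces: list[IntensityTrace] | IntensityTrace, path: str | Path) -> Path:
    if isinstance(traces, IntensityTrace):
        traces = [traces]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.concat([tr.to_frame() for tr in traces], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_traces_csv(path: str | Path, fps: float | None = None) -> list[IntensityTrace]:
    """Read one trace per distinct ROI id, preserving file order."""
    df = pd.read_csv(path)
    missing = set(_TRACE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} missing columns {sorted(missing)}")
    traces = []
    for roi_id in df["roi_id"].unique():
        sub = df[df["roi_id"] == roi_id]
        t = sub["t_s"].to_numpy(dtype=float)
        zone = None
        if "zone" in sub.columns and not sub["zone"].isna().all():
            zone = int(sub["zone"].iloc[0])
        traces.append(
            IntensityTrace(
                roi_id=str(roi_id),
                t=t,
                intensity=sub["intensity_gu"].to_numpy(dtype=float),
                fps=fps if fps is not None else _infer_fps(t),
                zone=zone,
            )
        )
    return traces


def write_synced_csv(series: SyncedSeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.to_frame().to_csv(path, index=False, float_format="%.6f")
    return path


def read_synced_csv(path: str | Path) -> SyncedSeries:
    df = pd.read_csv(path)
    df = df.rename(
        columns={
            "t_s": "t",
            "intensity_gu": "intensity",
            "distance_mm": "distance",
            "velocity_mm_s": "velocity",
            "angle_deg": "angle",
        }
    )
    return SyncedSeries(data=df, provenance={"source": str(path)})


def write_frame_png(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
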