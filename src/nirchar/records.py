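"""In-memory containers shared across the pipeline stages.

All times are seconds from the start of the respective recording, all
distances millimetres, all intensities displayed grayscale units (g.u.).
The pose clock (electromagnetic tracker, ~40 fps) and the video clock
(22-30 fps) are independent until :func:`nirchar.sync.synchronize` aligns
them on the tap artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrackTruth", "PoseTrack", "IntensityTrace", "SyncedSeries"]


@dataclass(frozen=True)
class TrackTruth:
    """Generator ground truth attached to a synthetic pose track.

    ``knot_t``/``knot_d`` define the noiseless piecewise-linear distance
    schedule; ``segments`` lists ``(t_start, t_end, kind)`` with kind in
    ``{"dwell", "transit"}``.
    """

    knot_t: np.ndarray
    knot_d: np.ndarray
    segments: tuple[tuple[float, float, str], ...]

    def distance_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.knot_t, self.knot_d)


@dataclass
class PoseTrack:
    """Timestamped scope-tip pose relative to the plate-origin sensor."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    angle: np.ndarray
    fps: float
    tap_time: float | None = None
    truth: TrackTruth | None = None

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "z", "angle"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if any(getattr(self, k).size != n for k in ("x", "y", "z", "angle")):
            raise ValueError("pose channel lengths differ")
        if n and not np.all(np.diff(self.t) > 0):
            raise ValueError("pose timestamps must be strictly increasing")
        if not all(
            np.isfinite(getattr(self, k)).all() for k in ("t", "x", "y", "z", "angle")
        ):
            raise ValueError("pose coordinates must be finite")

    def __len__(self) -> int:
        return self.t.size

    @property
    def distance(self) -> np.ndarray:
        """3D Euclidean distance of the scope tip from the origin sensor."""
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "x_mm": self.x,
                "y_mm": self.y,
                "z_mm": self.z,
                "angle_deg": self.angle,
            }
        )


@dataclass
class IntensityTrace:
    """Per-ROI displayed fluorescence intensity versus video time."""

    roi_id: str
    t: np.ndarray
    intensity: np.ndarray
    fps: float
    zone: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.size != self.intensity.size:
            raise ValueError("trace channel lengths differ")
        if self.t.size and not np.all(np.diff(self.t) > 0):
            raise ValueError("trace timestamps must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"t_s": self.t, "roi_id": self.roi_id, "intensity_gu": self.intensity}
        )
        if self.zone is not None:
            df["zone"] = self.zone
        return df


@dataclass
class SyncedSeries:
    """Pose and intensity merged onto the video timebase.

    ``data`` holds one record per retained video frame with columns
    ``t, intensity, distance, velocity, angle, direction``; ``direction``
    is one of ``{"approach", "retreat", "static"}`` from the sign of a
    smoothed distance derivative.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    _COLUMNS = ("t", "intensity", "distance", "velocity", "angle", "direction")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"SyncedSeries missing columns {sorted(missing)}")
        if np.any(self.data["distance"].to_numpy() < 0):
            raise ValueError("distance must be non-negative")

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        df = self.data.rename(
            columns={
                "t": "t_s",
                "intensity": "intensity_gu",
                "distance": "distance_mm",
                "velocity": "velocity_mm_s",
                "angle": "angle_deg",
            }
        )
        return df[
            ["t_s", "intensity_gu", "distance_mm", "velocity_mm_s", "angle_deg", "direction"]
        ]
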