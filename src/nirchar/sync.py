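"""Clock alignment of pose and video streams, and related arithmetic.

The tracker and the camera record on independent clocks.  A deliberate
physical tap of the scope leaves a simultaneous artifact in both streams —
a positional spike in the pose track and a transient intensity dip in the
trace — whose detected times give the clock offset.  The pose channels are
then linearly interpolated onto the video frame times (never extrapolated)
to yield one merged record per retained frame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import IntensityTrace, PoseTrack, SyncedSeries
from .simulate import smoothed_direction

__all__ = [
    "TapNotFoundError",
    "NoOverlapError",
    "euclidean_distance",
    "detect_tap",
    "synchronize",
    "split_by_direction",
    "concentration_from_dose",
]


class TapNotFoundError(RuntimeError):
    """No sufficiently isolated deviation found; supply a manual tap time."""


class NoOverlapError(RuntimeError):
    """The shifted pose span and the video span do not overlap."""


def euclidean_distance(a, b) -> float | np.ndarray:
    """3D Euclidean distance between positions ``a`` and ``b`` (mm).

    Accepts single ``(x, y, z)`` triples or ``(n, 3)`` arrays.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("positions must be finite")
    if a.shape[-1] != 3 or b.shape[-1] != 3:
        raise ValueError("positions must have 3 coordinates")
    d = np.sqrt(np.sum((a - b) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


def _tap_signal(source: PoseTrack | IntensityTrace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(source, PoseTrack):
        return source.t, source.distance
    # log-intensity makes the tap's transient dim level-independent, so it
    # stands out even when the tap lands at a low-intensity distance
    return source.t, np.log1p(source.intensity)


def detect_tap(
    source: PoseTrack | IntensityTrace,
    threshold: float = 6.0,
    manual_time: float | None = None,
) -> float:
    """Locate the synchronization tap in a pose track or intensity trace.

    The tap shows up as the largest isolated jump in the stream's first
    difference.  The difference is first detrended with a centered rolling
    median (~0.5 s) so steady hand motion — which shifts the whole local
    difference level — does not mask the one-sample jolt; a robust z-score
    (scaled MAD) of the detrended difference above ``threshold`` flags
    candidates and the largest wins.  ``manual_time`` always takes
    precedence and bypasses detection entirely.
    """
    if manual_time is not None:
        return float(manual_time)
    t, sig = _tap_signal(source)
    if t.size < 3 or t[-1] - t[0] < 2.0:
        raise ValueError("recording too short for tap detection (< 2 s)")
    diff = np.diff(sig)
    fps = 1.0 / float(np.median(np.diff(t)))
    win = max(3, int(round(0.5 * fps)) | 1)
    local_med = (
        pd.Series(diff).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    resid = diff - local_med
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad if mad > 0 else np.std(resid)
    if scale == 0:
        raise TapNotFoundError("constant signal: no tap artifact present")
    z = resid / scale
    candidates = np.flatnonzero(np.abs(z) > threshold)
    if candidates.size == 0:
        raise TapNotFoundError(
            f"no first-difference deviation above robust z = {threshold}"
        )
    # the artifact produces a tight cluster of anomalous steps (entry and
    # exit edges); anchor on the strongest, then report the onset: the
    # sample the cluster's first anomalous step lands on
    strongest = candidates[int(np.argmax(np.abs(z[candidates])))]
    cluster = candidates[np.abs(t[candidates] - t[strongest]) <= 0.18]
    return float(t[int(cluster.min()) + 1])


def synchronize(
    trace: IntensityTrace,
    track: PoseTrack,
    tap_trace: float | None = None,
    tap_track: float | None = None,
    smooth_s: float = 0.5,
    static_threshold: float = 2.0,
    tap_threshold: float = 6.0,
    mask_tap_s: float = 0.2,
) -> SyncedSeries:
    """Merge a trace and a pose track onto the video timebase.

    Pose timestamps are shifted by ``tap_trace - tap_track`` (taps detected
    automatically when not given), distance and angle are linearly
    interpolated at each video frame time, frames outside the shifted pose
    span are dropped, and frames within ``mask_tap_s`` of the tap are
    removed so the injected artifact does not enter the analysis.
    Per-frame velocity is ``|Δdistance| / Δt``; motion direction comes from
    the sign of a moving-average-smoothed distance derivative.
    """
    if tap_trace is None:
        tap_trace = detect_tap(trace, threshold=tap_threshold)
    if tap_track is None:
        tap_track = detect_tap(track, threshold=tap_threshold)
    if not (trace.t[0] <= tap_trace <= trace.t[-1]):
        raise ValueError("tap_trace outside the trace recording")
    if not (track.t[0] <= tap_track <= track.t[-1]):
        raise ValueError("tap_track outside the pose recording")

    shift = tap_trace - tap_track
    pose_t = track.t + shift
    keep = (trace.t >= pose_t[0]) & (trace.t <= pose_t[-1])
    if mask_tap_s > 0:
        keep &= np.abs(trace.t - tap_trace) > mask_tap_s
    t = trace.t[keep]
    if t.size == 0:
        raise NoOverlapError("no video frames inside the shifted pose span")

    distance = np.interp(t, pose_t, track.distance)
    angle = np.interp(t, pose_t, track.angle)
    intensity = trace.intensity[keep]

    velocity = np.zeros_like(t)
    if t.size > 1:
        velocity[1:] = np.abs(np.diff(distance)) / np.diff(t)
    direction, _ = smoothed_direction(
        t, distance, smooth_s=smooth_s, static_threshold=static_threshold
    )

    data = pd.DataFrame(
        {
            "t": t,
            "intensity": intensity,
            "distance": distance,
            "velocity": velocity,
            "angle": angle,
            "direction": direction,
        }
    )
    return SyncedSeries(
        data=data,
        provenance={
            "trace_id": trace.roi_id,
            "tap_trace_s": float(tap_trace),
            "tap_track_s": float(tap_track),
            "shift_s": float(shift),
            "n_dropped": int(np.count_nonzero(~keep)),
        },
    )


def split_by_direction(
    series: SyncedSeries,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition frames into (approach, retreat); static frames excluded."""
    df = series.data
    return (
        df[df["direction"] == "approach"].reset_index(drop=True),
        df[df["direction"] == "retreat"].reset_index(drop=True),
    )


def concentration_from_dose(
    dose_mg_per_kg: float, weight_kg: float, blood_volume_ml_per_kg: float
) -> float:
    """Blood concentration (mg/ml) of a weight-based intravenous dose.

    ``(dose x weight) / (blood_volume x weight)`` — the weight cancels, so
    the concentration is ``dose / blood_volume``; e.g. 0.1 mg/kg in a 70 kg
    subject with 70 ml/kg blood volume is 7 mg in 4.9 l = 0.0014 mg/ml.
    """
    if dose_mg_per_kg <= 0 or weight_kg <= 0 or blood_volume_ml_per_kg <= 0:
        raise ValueError("dose, weight and blood volume must be positive")
    return (dose_mg_per_kg * weight_kg) / (blood_volume_ml_per_kg * weight_kg)
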