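"""Synthetic pose-track, intensity-trace and frame generation.

The generator emulates the bench study's recording setup: an
electromagnetic tracker streams the scope-tip pose at ~40 fps while the
camera's displayed fluorescence is quantified per ROI at video rate.  Both
streams carry a deliberate *tap* artifact (a positional spike and a
transient intensity dip) so the two independent clocks can be aligned
post hoc, exactly as the downstream synchronization stage expects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import WellPlateGeometry
from .presets import CameraPreset, MotionProfile
from .records import IntensityTrace, PoseTrack, TrackTruth

__all__ = [
    "generate_pose_track",
    "generate_intensity_trace",
    "render_frame",
    "FrameRender",
    "smoothed_direction",
]

#: Video frames dimmed by the tap, and the dim factor applied to them.
TAP_DIP_FRAMES = 3
TAP_DIP_FACTOR = 0.25


def smoothed_direction(
    t: np.ndarray,
    distance: np.ndarray,
    smooth_s: float = 0.5,
    static_threshold: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify each frame as approach / retreat / static.

    The distance signal is smoothed with a centered moving average over
    ``smooth_s`` seconds before differentiating; frames whose smoothed
    derivative magnitude falls below ``static_threshold`` (mm/s) are
    static.  Negative derivative (closing on the target) is *approach*.

    Returns ``(direction, smoothed_derivative)``.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(distance, dtype=float)
    if t.size < 2:
        return np.array(["static"] * t.size, dtype=object), np.zeros(t.size)
    dt = float(np.median(np.diff(t)))
    half = max(1, int(round(smooth_s / dt / 2)))
    width = 2 * half + 1
    padded = np.pad(d, half, mode="edge")
    kernel = np.ones(width) / width
    smooth = np.convolve(padded, kernel, mode="valid")
    deriv = np.gradient(smooth, t)
    direction = np.where(
        np.abs(deriv) < static_threshold,
        "static",
        np.where(deriv < 0, "approach", "retreat"),
    ).astype(object)
    return direction, deriv


def _distance_schedule(profile: MotionProfile) -> TrackTruth:
    """Piecewise-linear distance-versus-time knots for a motion profile."""
    wp = [float(w) for w in profile.distance_waypoints]
    knot_t: list[float] = [0.0]
    knot_d: list[float] = [wp[0]]
    segments: list[tuple[float, float, str]] = []

    def dwell(duration: float) -> None:
        t0 = knot_t[-1]
        knot_t.append(t0 + duration)
        knot_d.append(knot_d[-1])
        segments.append((t0, t0 + duration, "dwell"))

    def transit(target: float) -> None:
        t0, d0 = knot_t[-1], knot_d[-1]
        duration = abs(target - d0) / profile.mean_speed
        if duration <= 0:
            return
        knot_t.append(t0 + duration)
        knot_d.append(target)
        segments.append((t0, t0 + duration, "transit"))

    if profile.regime == "static_episodic":
        dwell(profile.dwell_s)
        for target in wp[1:]:
            transit(target)
            dwell(profile.dwell_s)
    else:  # continuous sweep, forth and back, until duration_s is covered
        if len(wp) == 1:
            dwell(profile.duration_s)
        else:
            path = wp[1:] + wp[-2::-1]  # forward then reverse, cyclic
            i = 0
            while knot_t[-1] < profile.duration_s:
                transit(path[i % len(path)])
                i += 1
    return TrackTruth(
        knot_t=np.asarray(knot_t),
        knot_d=np.asarray(knot_d),
        segments=tuple(segments),
    )


def generate_pose_track(profile: MotionProfile, seed: int) -> PoseTrack:
    """Simulate the tracker's pose stream for one motion profile.

    The scope tip follows the profile's distance schedule along a mostly
    vertical path with a few millimetres of slow lateral wobble, bounded
    angular wobble around perpendicular (90 deg), optional Gaussian
    positional noise, and a single-sample positional spike at
    ``profile.tap_time`` (the synchronization tap).
    """
    rng = np.random.default_rng(seed)
    truth = _distance_schedule(profile)
    total = float(truth.knot_t[-1])
    if not 0.0 < profile.tap_time < total:
        raise ValueError(
            f"tap_time {profile.tap_time} s not strictly inside the "
            f"{total:.2f} s recording"
        )
    n = int(np.floor(total * profile.pose_fps))  # half-open [0, total)
    t = np.arange(n) / profile.pose_fps
    d = truth.distance_at(t)

    w = profile.lateral_wobble_mm
    ph = rng.uniform(0, 2 * np.pi, size=2)
    x = w * np.sin(2 * np.pi * t / 7.3 + ph[0])
    y = w * np.sin(2 * np.pi * t / 9.1 + ph[1])
    z = np.sqrt(np.maximum(d**2 - x**2 - y**2, 0.0))
    if profile.noise_mm > 0:
        x = x + rng.normal(0, profile.noise_mm, n)
        y = y + rng.normal(0, profile.noise_mm, n)
        z = z + rng.normal(0, profile.noise_mm, n)

    # tap artifact: one pose sample kicked well clear of its neighbours
    tap_idx = int(np.argmin(np.abs(t - profile.tap_time)))
    z[tap_idx] += profile.tap_amplitude_mm

    angle = 90.0 + profile.angle_amplitude_deg * np.sin(
        2 * np.pi * t / profile.angle_period_s + rng.uniform(0, 2 * np.pi)
    )
    if profile.noise_mm > 0:
        angle = angle + rng.normal(0, 0.2, n)

    return PoseTrack(
        t=t, x=x, y=y, z=z, angle=angle,
        fps=profile.pose_fps, tap_time=float(t[tap_idx]), truth=truth,
    )


def generate_intensity_trace(
    preset: CameraPreset,
    track: PoseTrack,
    roi_position: float = 0.0,
    seed: int = 0,
    roi_id: str = "roi0",
    zone: int | None = None,
    tap_dip: bool = True,
) -> IntensityTrace:
    """Simulate one ROI's displayed-intensity time series for a pose track.

    The camera-target distance is interpolated from the track (ground-truth
    schedule when available) onto the video timebase; the preset's response
    law — split by motion direction for hysteresis presets — is scaled by
    the vignette factor at the ROI's screen radius ``roi_position``
    (fraction of the plate half-diagonal), Gaussian sensor noise is added,
    and the result is clipped to the 8-bit display range.
    """
    if len(track) < 2:
        raise ValueError("pose track too short to derive a video timebase")
    rng = np.random.default_rng(seed)
    n = int(np.floor(track.duration * preset.fps)) + 1
    t = track.t[0] + np.arange(n) / preset.fps

    if track.truth is not None:
        distance = track.truth.distance_at(t)
    else:
        distance = np.interp(t, track.t, track.distance)

    direction = None
    if preset.hysteresis:
        direction, _ = smoothed_direction(t, distance)

    noiseless = preset.law_value(distance, direction)
    noiseless = noiseless * preset.vignette.factor(roi_position)
    noiseless = np.clip(noiseless, 0.0, preset.saturation_cap)

    if tap_dip and track.tap_time is not None:
        in_dip = (t >= track.tap_time) & (t < track.tap_time + TAP_DIP_FRAMES / preset.fps)
        noiseless = np.where(in_dip, noiseless * TAP_DIP_FACTOR, noiseless)

    intensity = noiseless
    if preset.noise_sigma > 0:
        intensity = intensity + rng.normal(0, preset.noise_sigma, n)
    intensity = np.clip(intensity, 0.0, preset.saturation_cap)

    return IntensityTrace(
        roi_id=roi_id, t=t, intensity=intensity, fps=preset.fps, zone=zone
    )


@dataclass(frozen=True)
class FrameRender:
    """A rendered monochrome frame plus its view metadata."""

    image: np.ndarray  # uint8, (image_size, image_size)
    partial_view: bool
    mm_per_px: float
    visible_radius_mm: float


def render_frame(
    plate: WellPlateGeometry,
    preset: CameraPreset,
    camera_distance: float,
    image_size: int = 256,
    seed: int | None = None,
) -> FrameRender:
    """Render the plate as seen by an ideal pinhole camera above its center.

    The circular field of view at ``camera_distance`` has radius
    ``distance * tan(half_fov)`` in the plate plane; wells are filled
    circles at the preset law value times the vignette factor at each
    well's radial position.  ``partial_view`` is set when the plate's
    corners fall outside the field (camera closer than the geometric IOD).
    """
    if camera_distance <= 0:
        raise ValueError("camera_distance must be positive")
    visible_r = camera_distance * np.tan(np.radians(preset.half_fov_deg))
    partial = bool(plate.half_diagonal > visible_r * (1 + 1e-12))

    mm_per_px = 2 * visible_r / image_size
    axis = (np.arange(image_size) + 0.5) * mm_per_px - visible_r
    X, Y = np.meshgrid(axis, axis)

    img = np.zeros((image_size, image_size), dtype=float)
    base = float(preset.law_value(camera_distance))
    r_well = plate.well_diameter / 2
    for i in range(plate.grid**2):
        wx, wy = plate.well_center(i)
        disk = (X - wx) ** 2 + (Y - wy) ** 2 <= r_well**2
        img[disk] = base * float(preset.vignette.factor(plate.radius_fraction(i)))

    img[X**2 + Y**2 > visible_r**2] = 0.0  # outside circular field

    if preset.noise_sigma > 0 and seed is not None:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0, preset.noise_sigma, img.shape)

    img = np.clip(img, 0, 255).round().astype(np.uint8)
    return FrameRender(
        image=img,
        partial_view=partial,
        mm_per_px=mm_per_px,
        visible_radius_mm=float(visible_r),
    )
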