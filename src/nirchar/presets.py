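"""Synthetic camera presets and scope motion profiles.

A :class:`CameraPreset` captures how a clinical near-infrared system maps
camera-target distance to displayed grayscale intensity:

* ``inverse_square`` — ``I(x) = A/(x - C)^2 + B`` (typical laparoscopes),
* ``sigmoid``        — ``I(x) = A/(1 + exp(B (x - C))) + D`` with ``B > 0``
  so the high plateau sits at short distance,
* ``flat``           — ``I(x) = A x + B`` with a near-zero slope,
  emulating distance-compensated systems whose displayed signal varies
  within only a few grayscale units across the working range.

Direction-dependent *hysteresis* (observed on one laparoscopic system)
switches the law per frame: sigmoid while approaching the target,
inverse-square while retreating.

A radial vignette factor multiplies the law; ``central_bright`` dims the
periphery, ``peripheral_bright`` dims the center (software-compensated open
systems), ``mid_bright`` peaks at mid radius.

A :class:`MotionProfile` describes how the scope tip is moved above the
plate: episodic holds at set distances, continuous slow sweeps, or
continuous fast sweeps, plus a deliberate tap used later to align the pose
and video clocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "VignetteProfile",
    "CameraPreset",
    "MotionProfile",
    "BUILTIN_PRESETS",
    "get_preset",
    "load_preset",
    "default_motion_profile",
    "load_motion_profile",
    "TRACKING_RANGE_MM",
]

#: Vertical measurement volume of the electromagnetic field generator, mm.
TRACKING_RANGE_MM = (120.0, 600.0)

LAWS = ("inverse_square", "sigmoid", "flat")
VIGNETTE_MODES = ("none", "central_bright", "peripheral_bright", "mid_bright")
REGIMES = ("static_episodic", "slow", "fast")


@dataclass(frozen=True)
class VignetteProfile:
    """Radial screen-intensity falloff model ``g(r)``, r = radius fraction.

    ``central_bright``:    g(r) = 1 - k * r**p
    ``peripheral_bright``: g(r) = 1 - k * (1 - r)**p
    ``mid_bright``:        g(r) = 1 - k * |2 r - 1|**p
    ``none``:              g(r) = 1
    """

    mode: str = "none"
    k: float = 0.0
    p: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in VIGNETTE_MODES:
            raise ValueError(f"unknown vignette mode {self.mode!r}")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("vignette strength k must lie in [0, 1]")
        if self.p <= 0:
            raise ValueError("vignette exponent p must be > 0")

    def factor(self, radius_fraction):
        r = np.clip(np.asarray(radius_fraction, dtype=float), 0.0, 1.0)
        if self.mode == "none":
            return np.ones_like(r)
        if self.mode == "central_bright":
            return 1.0 - self.k * r**self.p
        if self.mode == "peripheral_bright":
            return 1.0 - self.k * (1.0 - r) ** self.p
        return 1.0 - self.k * np.abs(2.0 * r - 1.0) ** self.p


@dataclass(frozen=True)
class CameraPreset:
    """Synthetic model of one NIR camera system's displayed response."""

    name: str
    law: str
    params: dict[str, float]
    hysteresis: bool = False
    retreat_params: dict[str, float] | None = None
    vignette: VignetteProfile = field(default_factory=VignetteProfile)
    noise_sigma: float = 1.5
    saturation_cap: float = 255.0
    fps: float = 30.0
    compensated_range: float = 4.23
    half_fov_deg: float = 35.0

    def __post_init__(self) -> None:
        if self.law not in LAWS:
            raise ValueError(f"unknown law {self.law!r}")
        if self.hysteresis and self.law != "sigmoid":
            raise ValueError("hysteresis is only meaningful for the sigmoid law")
        if self.hysteresis and not self.retreat_params:
            raise ValueError("hysteresis preset needs retreat_params (inverse-square)")
        if self.fps <= 0 or self.noise_sigma < 0 or self.saturation_cap <= 0:
            raise ValueError("fps, noise_sigma, saturation_cap out of range")

    # -- response laws ----------------------------------------------------

    @staticmethod
    def _inverse_square(x, p):
        return p["A"] / (x - p["C"]) ** 2 + p["B"]

    @staticmethod
    def _sigmoid(x, p):
        return p["A"] / (1.0 + np.exp(p["B"] * (x - p["C"]))) + p["D"]

    def law_value(self, distance_mm, direction=None) -> np.ndarray:
        """Raw response-law value at ``distance_mm`` (g.u., unclipped).

        The display's [0, saturation_cap] clip is applied downstream,
        *after* the vignette factor, mirroring the optical path (radial
        light falloff precedes sensor/display saturation).  ``direction``
        (array of ``{"approach", "retreat", "static"}``) is only consulted
        for hysteresis presets: retreat frames follow the inverse-square
        retreat law, all others the sigmoid.
        """
        x = np.asarray(distance_mm, dtype=float)
        if self.law == "flat":
            y = self.params["A"] * x + self.params["B"]
        elif self.law == "inverse_square":
            y = self._inverse_square(x, self.params)
        else:
            y = self._sigmoid(x, self.params)
            if self.hysteresis and direction is not None:
                retreat = np.asarray(direction) == "retreat"
                if retreat.any():
                    y = np.where(
                        retreat, self._inverse_square(x, self.retreat_params), y
                    )
        return np.asarray(y, dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vignette"] = asdict(self.vignette)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CameraPreset":
        d = dict(d)
        vig = d.pop("vignette", None)
        if isinstance(vig, dict):
            d["vignette"] = VignetteProfile(**vig)
        elif vig is not None:
            d["vignette"] = vig
        return cls(**d)


@dataclass(frozen=True)
class MotionProfile:
    """Scope-tip motion schedule above the plate.

    ``static_episodic`` alternates zero-velocity dwells at each waypoint
    with transits between them; ``slow``/``fast`` sweep continuously back
    and forth along the waypoint list at ``mean_speed``.
    """

    regime: str = "slow"
    distance_waypoints: tuple[float, ...] = (140.0, 440.0)
    dwell_s: float = 4.0
    mean_speed: float = 20.0
    angle_amplitude_deg: float = 6.0
    angle_period_s: float = 11.0
    pose_fps: float = 40.0
    tap_time: float = 2.0
    duration_s: float = 60.0
    noise_mm: float = 0.0
    tap_amplitude_mm: float = 15.0
    lateral_wobble_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown motion regime {self.regime!r}")
        lo, hi = TRACKING_RANGE_MM
        wp = np.asarray(self.distance_waypoints, dtype=float)
        if wp.size == 0:
            raise ValueError("at least one distance waypoint required")
        if np.any(wp < lo) or np.any(wp > hi):
            raise ValueError(
                f"waypoints outside the tracked volume {lo:.0f}-{hi:.0f} mm"
            )
        if self.mean_speed <= 0 or self.pose_fps <= 0:
            raise ValueError("mean_speed and pose_fps must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distance_waypoints"] = list(self.distance_waypoints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MotionProfile":
        d = dict(d)
        if "distance_waypoints" in d:
            d["distance_waypoints"] = tuple(d["distance_waypoints"])
        return cls(**d)


# -- built-in presets -----------------------------------------------------
# Numeric parameters are calibrated so synthetic outputs land on the scale
# of the published system measurements (peak intensities and ranges) within
# the 120-600 mm tracked volume; see docs/methods.md.

BUILTIN_PRESETS: dict[str, CameraPreset] = {
    # laparoscope, inverse-square falloff, centrally bright
    "pnl_like": CameraPreset(
        name="pnl_like",
        law="inverse_square",
        params={"A": 1.03e6, "B": 2.0, "C": 40.0},
        vignette=VignetteProfile("central_bright", k=0.35, p=2.0),
        noise_sigma=1.5,
        fps=29.97,
        half_fov_deg=35.0,
    ),
    # laparoscope with direction-dependent response: sigmoid on approach,
    # inverse-square on retreat; strongest central brightening
    "eml_like": CameraPreset(
        name="eml_like",
        law="sigmoid",
        params={"A": 70.0, "B": 0.04, "C": 160.0, "D": 4.0},
        hysteresis=True,
        retreat_params={"A": 6.0e5, "B": 3.0, "C": 30.0},
        vignette=VignetteProfile("central_bright", k=0.55, p=2.0),
        noise_sigma=1.5,
        fps=22.0,
        half_fov_deg=30.0,
    ),
    # arm-mounted open system: distance-compensated flat response,
    # slightly brighter periphery
    "emo_like": CameraPreset(
        name="emo_like",
        law="flat",
        params={"A": -0.01, "B": 228.0},
        vignette=VignetteProfile("peripheral_bright", k=0.012, p=2.0),
        noise_sigma=1.5,
        fps=22.0,
        compensated_range=4.23,
        half_fov_deg=20.0,
    ),
    # handheld open system: inverse-square falloff, mid-zone brightest
    "sso_like": CameraPreset(
        name="sso_like",
        law="inverse_square",
        params={"A": 2.1e6, "B": 5.0, "C": 50.0},
        vignette=VignetteProfile("mid_bright", k=0.2, p=1.0),
        noise_sigma=3.0,
        fps=30.0,
        half_fov_deg=22.0,
    ),
}


def get_preset(name: str) -> CameraPreset:
    try:
        return BUILTIN_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; built-ins: {sorted(BUILTIN_PRESETS)}"
        ) from None


def load_preset(source: str | Path | dict) -> CameraPreset:
    """Load a preset from a built-in name, a YAML/JSON file, or a dict."""
    if isinstance(source, dict):
        return CameraPreset.from_dict(source)
    if isinstance(source, str) and source in BUILTIN_PRESETS:
        return BUILTIN_PRESETS[source]
    path = Path(source)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return CameraPreset.from_dict(data)


_REGIME_DEFAULTS = {
    # episodic holds at set distances, out and back so both motion
    # directions occur; transits at a brisk hand speed
    "static_episodic": dict(
        distance_waypoints=(
            140.0, 200.0, 260.0, 320.0, 380.0, 440.0, 320.0, 200.0, 140.0,
        ),
        dwell_s=4.0,
        mean_speed=100.0,
    ),
    # continuous slow sweep, ~20 mm/s
    "slow": dict(distance_waypoints=(140.0, 440.0), mean_speed=20.0),
    # continuous fast sweep, ~170 mm/s
    "fast": dict(distance_waypoints=(140.0, 440.0), mean_speed=170.0),
}


def default_motion_profile(regime: str, **overrides) -> MotionProfile:
    """Study-condition motion profile for one of the three regimes."""
    if regime not in _REGIME_DEFAULTS:
        raise ValueError(f"unknown motion regime {regime!r}")
    kw = dict(_REGIME_DEFAULTS[regime])
    kw.update(overrides)
    return MotionProfile(regime=regime, **kw)


def load_motion_profile(source: str | Path | dict) -> MotionProfile:
    if isinstance(source, dict):
        return MotionProfile.from_dict(source)
    path = Path(source)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return MotionProfile.from_dict(data)
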