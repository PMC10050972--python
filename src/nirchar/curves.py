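"""Distance-intensity curve models and ideal-fluorescence-distance (IFD).

Three response families describe how displayed intensity I (g.u.) varies
with camera-target distance x (mm):

* linear          ``I = a x + b``             (flat, distance-compensated)
* inverse-square  ``I = A/(x - C)^2 + B``
* sigmoid         ``I = A/(1 + exp(B (x - C))) + D``  with ``B > 0`` so the
  high plateau sits at short distance.

The IFD is the working distance that avoids both the saturation-prone
proximal region and the low-SNR distal region.  For inverse-square data it
is the breakpoint of a piecewise *double line* ``y = max(y1, y2)``:
``IFD = (d - b)/(a - c)`` for lines ``y1 = a x + b`` and ``y2 = c x + d``.
For sigmoid data it is the zero of the sigmoid's third derivative beyond
the near plateau, which sits at ``C - ln(2 + sqrt(3))/B ~= C - 1.317/B``
where the curve passes 79% of its total range; the mirror-image threshold
``C + 1.317/B`` marks the far tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "SIGMOID_THRESHOLD",
    "SIGMOID_RANGE_FRACTION",
    "CurveFit",
    "IFDResult",
    "DegenerateDataError",
    "FitError",
    "NoTransitionError",
    "OrientationError",
    "fit_linear",
    "fit_inverse_square",
    "fit_sigmoid",
    "fit_double_line",
    "ifd_sigmoid",
    "select_family",
]

#: ln(2 + sqrt(3)) = 1.3170 (4 d.p.) — the offset, in units of 1/B, of the
#: sigmoid's third-derivative zeros from its center C.
SIGMOID_THRESHOLD = math.log(2.0 + math.sqrt(3.0))

#: Normalized sigmoid value at the near-side third-derivative zero:
#: (3 + sqrt(3))/6 = 0.7887, i.e. "79% of the total range".
SIGMOID_RANGE_FRACTION = (3.0 + math.sqrt(3.0)) / 6.0


class DegenerateDataError(ValueError):
    """Input data cannot constrain the requested model."""


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge from every start."""


class NoTransitionError(RuntimeError):
    """Double-line segments are parallel: no breakpoint exists."""


class OrientationError(RuntimeError):
    """Sigmoid fit is not oriented with its high plateau at short distance."""


@dataclass
class CurveFit:
    """A fitted distance-intensity model."""

    family: str  # linear | inverse_square | sigmoid | double_line
    params: dict[str, float]
    r_squared: float  # NaN when SS_tot = 0 (constant signal)
    n_points: int
    warnings: list[str] = field(default_factory=list)

    def predict(self, d) -> np.ndarray:
        x = np.asarray(d, dtype=float)
        p = self.params
        if self.family == "linear":
            return p["slope"] * x + p["intercept"]
        if self.family == "inverse_square":
            return p["A"] / (x - p["C"]) ** 2 + p["B"]
        if self.family == "sigmoid":
            return p["A"] * expit(-p["B"] * (x - p["C"])) + p["D"]
        if self.family == "double_line":
            return np.maximum(p["a"] * x + p["b"], p["c"] * x + p["d"])
        raise ValueError(f"unknown family {self.family!r}")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": {k: float(v) for k, v in self.params.items()},
            "r_squared": None if np.isnan(self.r_squared) else float(self.r_squared),
            "n_points": int(self.n_points),
            "warnings": list(self.warnings),
        }


@dataclass
class IFDResult:
    """An ideal fluorescence distance extracted from a fitted curve."""

    method: str  # double_line | sigmoid_transition | sigmoid_alternative
    ifd: float  # mm
    source_fit: CurveFit
    value_at_ifd: float | None = None  # fitted intensity at the IFD, g.u.

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ifd_mm": float(self.ifd),
            "value_at_ifd_gu": None
            if self.value_at_ifd is None
            else float(self.value_at_ifd),
            "fit_family": self.source_fit.family,
        }


# -- helpers --------------------------------------------------------------


def _clean(d, I, saturation_cap):
    d = np.asarray(d, dtype=float).ravel()
    I = np.asarray(I, dtype=float).ravel()
    if d.size != I.size:
        raise ValueError("d and I must have equal length")
    if not (np.isfinite(d).all() and np.isfinite(I).all()):
        raise ValueError("d and I must be finite")
    warnings = []
    if saturation_cap is not None:
        keep = I < saturation_cap
        n_sat = int(np.count_nonzero(~keep))
        if n_sat:
            warnings.append(f"saturated_excluded:{n_sat}")
            d, I = d[keep], I[keep]
    return d, I, warnings


def _r_squared(I, pred) -> tuple[float, bool]:
    ss_res = float(np.sum((I - pred) ** 2))
    ss_tot = float(np.sum((I - np.mean(I)) ** 2))
    if ss_tot == 0.0:
        return float("nan"), True
    return 1.0 - ss_res / ss_tot, False


# -- fitting --------------------------------------------------------------


def fit_linear(d, I, saturation_cap: float | None = None) -> CurveFit:
    """Ordinary least-squares line ``I = slope * d + intercept``."""
    d, I, warn = _clean(d, I, saturation_cap)
    if d.size < 3:
        raise DegenerateDataError("need >= 3 points for a line")
    if np.ptp(d) == 0:
        raise DegenerateDataError("degenerate abscissa: all distances equal")
    slope, intercept = np.polyfit(d, I, 1)
    r2, const = _r_squared(I, slope * d + intercept)
    if const:
        warn = warn + ["constant_signal"]
    return CurveFit(
        family="linear",
        params={"slope": float(slope), "intercept": float(intercept)},
        r_squared=r2,
        n_points=d.size,
        warnings=warn,
    )


def _inv_sq(x, A, B, C):
    return A / (x - C) ** 2 + B


def fit_inverse_square(
    d, I, init: dict | None = None, saturation_cap: float | None = None
) -> CurveFit:
    """Nonlinear least squares for ``I = A/(d - C)^2 + B``.

    The pole C is constrained below the data range.  Multiple heuristic
    starts are tried and the best converged solution (by residual sum of
    squares) wins.
    """
    d, I, warn = _clean(d, I, saturation_cap)
    if d.size < 4:
        raise DegenerateDataError("need >= 4 points for the inverse-square fit")
    span = float(np.ptp(d)) or 1.0
    dmin = float(np.min(d))
    c_max = dmin - 1e-9 * span
    bounds = ([0.0, -np.inf, -np.inf], [np.inf, np.inf, c_max])

    i_near = int(np.argmin(d))
    b0 = float(np.min(I))
    starts = []
    if init is not None:
        starts.append((init["A"], init["B"], init["C"]))
    for c0 in (dmin - span / 10, dmin - span / 2, dmin - span, dmin - 5 * span, 0.0):
        if c0 >= c_max:
            continue
        a0 = max((I[i_near] - b0) * (d[i_near] - c0) ** 2, 1e-6)
        starts.append((a0, b0, c0))

    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _inv_sq, d, I, p0=p0, bounds=bounds,
                xtol=1e-8, ftol=1e-8, maxfev=10_000,
            )
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((I - _inv_sq(d, *popt)) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt)
    if best is None:
        raise FitError(
            f"inverse-square fit failed from {len(starts)} starts "
            f"(n={d.size}, d in [{dmin:.1f}, {dmin + span:.1f}] mm)"
        )
    A, B, C = best[1]
    r2, const = _r_squared(I, _inv_sq(d, A, B, C))
    if const:
        warn = warn + ["constant_signal"]
    return CurveFit(
        family="inverse_square",
        params={"A": float(A), "B": float(B), "C": float(C)},
        r_squared=r2,
        n_points=d.size,
        warnings=warn,
    )


def _sigmoid(x, A, B, C, D):
    # expit keeps the evaluation overflow-free for large |B (x - C)|
    return A * expit(-B * (x - C)) + D


def fit_sigmoid(
    d, I, init: dict | None = None, saturation_cap: float | None = None
) -> CurveFit:
    """Nonlinear least squares for ``I = A/(1 + exp(B (d - C))) + D``.

    The orientation with the high plateau at short distance is enforced by
    bounding ``A >= 0`` and ``B > 0`` rather than sign-flipping a converged
    mirror solution.
    """
    d, I, warn = _clean(d, I, saturation_cap)
    if d.size < 5:
        raise DegenerateDataError("need >= 5 points for the sigmoid fit")
    span = float(np.ptp(d)) or 1.0
    bounds = ([0.0, 1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf])

    d0v = float(np.min(I))
    a0 = float(np.ptp(I)) or 1.0
    half = d0v + a0 / 2
    c_half = float(d[np.argmin(np.abs(I - half))])
    starts = []
    if init is not None:
        starts.append((init["A"], init["B"], init["C"], init["D"]))
    for c0 in dict.fromkeys((c_half, float(np.median(d)))):
        for b0 in (2.0 / span, 10.0 / span, 40.0 / span):
            starts.append((a0, b0, c0, d0v))

    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _sigmoid, d, I, p0=p0, bounds=bounds,
                xtol=1e-8, ftol=1e-8, maxfev=10_000,
            )
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((I - _sigmoid(d, *popt)) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt)
    if best is None:
        raise FitError(f"sigmoid fit failed from {len(starts)} starts (n={d.size})")
    A, B, C, D = best[1]
    if B <= 0:
        raise OrientationError("fitted B <= 0 despite orientation bounds")
    r2, const = _r_squared(I, _sigmoid(d, A, B, C, D))
    if const:
        warn = warn + ["constant_signal"]
    return CurveFit(
        family="sigmoid",
        params={"A": float(A), "B": float(B), "C": float(C), "D": float(D)},
        r_squared=r2,
        n_points=d.size,
        warnings=warn,
    )


def fit_double_line(
    d, I, saturation_cap: float | None = None
) -> tuple[CurveFit, IFDResult]:
    """Piecewise two-line model ``y = max(y1, y2)`` by breakpoint search.

    Every split of the distance-sorted points into a left segment (>= 3
    points) and right segment (>= 3 points) is scored: each segment gets
    its own least-squares line and the candidate is judged by the residual
    sum of squares of the max-composite over *all* points.  Ties resolve
    toward the smaller breakpoint distance.  The IFD is the line
    intersection ``(d - b)/(a - c)``.
    """
    d, I, warn = _clean(d, I, saturation_cap)
    if d.size < 6:
        raise DegenerateDataError("need >= 6 points for the double-line fit")
    order = np.argsort(d, kind="stable")
    ds, Is = d[order], I[order]
    if np.ptp(ds) == 0:
        raise DegenerateDataError("degenerate abscissa: all distances equal")

    n = ds.size
    best = None  # (ss, k, line1, line2)
    for k in range(3, n - 2):  # left = [:k], right = [k:], ascending breakpoint
        a, b = np.polyfit(ds[:k], Is[:k], 1)
        c, dd = np.polyfit(ds[k:], Is[k:], 1)
        composite = np.maximum(a * ds + b, c * ds + dd)
        ss = float(np.sum((Is - composite) ** 2))
        if best is None or ss < best[0]:
            best = (ss, k, (a, b), (c, dd))

    ss, k, (a, b), (c, dd) = best
    if k == 3 or k == n - 3:
        warn = warn + ["single_regime"]
    if abs(a - c) <= 1e-12 * (abs(a) + abs(c) + 1.0):
        raise NoTransitionError("segments are parallel: no breakpoint")
    ifd = (dd - b) / (a - c)

    composite = np.maximum(a * ds + b, c * ds + dd)
    r2, const = _r_squared(Is, composite)
    if const:
        warn = warn + ["constant_signal"]
    fit = CurveFit(
        family="double_line",
        params={
            "a": float(a),
            "b": float(b),
            "c": float(c),
            "d": float(dd),
            "breakpoint_index": float(k),
        },
        r_squared=r2,
        n_points=n,
        warnings=warn,
    )
    result = IFDResult(
        method="double_line",
        ifd=float(ifd),
        source_fit=fit,
        value_at_ifd=float(a * ifd + b),
    )
    return fit, result


def ifd_sigmoid(fit: CurveFit, alternative: bool = False) -> IFDResult:
    """IFD from a sigmoid fit's third-derivative zero.

    ``IFD = C - 1.317/B`` at the near (transition) threshold where the
    curve sits at 79% of its range, or ``C + 1.317/B`` (``alternative``)
    at the mirrored far-tail threshold (21% of range).
    """
    if fit.family != "sigmoid":
        raise ValueError("ifd_sigmoid requires a sigmoid CurveFit")
    A, B, C, D = (fit.params[k] for k in "ABCD")
    if B <= 0:
        raise OrientationError("sigmoid fit has B <= 0")
    sign = 1.0 if alternative else -1.0
    ifd = C + sign * SIGMOID_THRESHOLD / B
    frac = 1.0 - SIGMOID_RANGE_FRACTION if alternative else SIGMOID_RANGE_FRACTION
    expected = D + A * frac
    value = float(fit.predict(ifd))
    if abs(value - expected) > 1e-3 * max(abs(A), 1.0):
        raise AssertionError("sigmoid threshold identity violated")
    return IFDResult(
        method="sigmoid_alternative" if alternative else "sigmoid_transition",
        ifd=float(ifd),
        source_fit=fit,
        value_at_ifd=value,
    )


def select_family(
    d,
    I,
    flat_range_threshold: float = 4.23,
    saturation_cap: float | None = None,
    smooth_frames: int = 21,
) -> dict:
    """Classify a distance-intensity series into its response family.

    The intensity is first smoothed with a ``smooth_frames`` moving average
    (the input is assumed to be in recording order) to measure the
    systematic signal range free of frame noise; a series whose robust
    smoothed range (0.5th-99.5th percentile) stays within
    ``flat_range_threshold`` g.u. is a flat, distance-compensated response
    and gets a linear fit.  Otherwise the inverse-square and sigmoid
    families are both fitted and the higher R-squared wins — except that a
    sigmoid whose fitted center C falls outside the observed distance span
    shows no plateau evidence (it merely mimics a monotone decay) and is
    flagged ``center_outside_data``, leaving it ineligible as the winner.

    Returns ``{"family": ..., "fits": {family: CurveFit}}``.
    """
    dc, Ic, _ = _clean(d, I, saturation_cap)
    w = max(1, min(smooth_frames, Ic.size))
    smooth = np.convolve(Ic, np.ones(w) / w, mode="valid")
    lo, hi = np.percentile(smooth, [0.5, 99.5])
    if hi - lo <= flat_range_threshold:
        return {"family": "linear", "fits": {"linear": fit_linear(dc, Ic)}}
    fits: dict[str, CurveFit] = {}
    for name, fn in (("inverse_square", fit_inverse_square), ("sigmoid", fit_sigmoid)):
        try:
            fits[name] = fn(dc, Ic)
        except (FitError, DegenerateDataError, OrientationError):
            continue
    if not fits:
        raise FitError("no nonlinear family converged")
    eligible = dict(fits)
    sig = fits.get("sigmoid")
    if sig is not None and not (np.min(dc) <= sig.params["C"] <= np.max(dc)):
        sig.warnings.append("center_outside_data")
        if len(eligible) > 1:
            del eligible["sigmoid"]
    family = max(eligible, key=lambda k: eligible[k].r_squared)
    return {"family": family, "fits": fits}
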