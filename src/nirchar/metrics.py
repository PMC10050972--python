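"""Rolling SNR, correlation reports, zone (CPR) statistics and IOD.

The rolling signal-to-noise ratio divides a 20-frame forward-window mean
of the displayed intensity by the same window's population standard
deviation.  Spearman correlations (SNR vs velocity, intensity residual vs
scope angle) are reported with the conventional effect-size labels at
|rho| cut-points 0.1 / 0.4 / 0.7 / 0.89.  The center-versus-periphery
(CPR) assessment averages the four wells of each zone frame-by-frame over
a one-second window and compares zones with Kruskal-Wallis plus
Bonferroni-corrected pairwise tests (Shapiro-Wilk normality recorded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .records import IntensityTrace, SyncedSeries
from .curves import CurveFit

__all__ = [
    "RollingSNR",
    "CorrelationReport",
    "ZoneReport",
    "IODNotReachedError",
    "rolling_snr",
    "categorize_rho",
    "velocity_snr_correlation",
    "angular_residual_analysis",
    "zone_cpr_analysis",
    "iod_empirical",
    "iod_geometric",
]


class IODNotReachedError(RuntimeError):
    """The full target was never visible in the recording."""


# -- rolling SNR ----------------------------------------------------------


@dataclass
class RollingSNR:
    """Forward-window rolling mean, SD and their ratio."""

    window: int
    rolling_mean: np.ndarray
    rolling_sd: np.ndarray
    snr: np.ndarray  # NaN where the window SD is zero
    mean_snr: float  # NaN when no window has positive SD
    n_zero_sd: int

    @property
    def constant_signal_warning(self) -> bool:
        return self.n_zero_sd > 0


def rolling_snr(
    trace: IntensityTrace | np.ndarray,
    window: int = 20,
    inclusive_window: bool = False,
) -> RollingSNR:
    """Rolling SNR of an intensity series.

    Window ``i`` covers the ``window`` frames starting at frame ``i`` (the
    as-printed 21-frame variant spanning ``j = i .. i+window`` is available
    via ``inclusive_window=True``); the SD uses divisor ``window``
    (population form) in both variants.  ``window`` windows are emitted for
    every frame ``i`` such that a full *next* window exists, i.e. the
    series yields ``N - window`` windows.  Windows with zero SD (constant
    or saturated signal) are excluded from the mean SNR and counted.
    """
    I = trace.intensity if isinstance(trace, IntensityTrace) else np.asarray(trace, float)
    w = window + 1 if inclusive_window else window
    if I.size <= window:
        raise ValueError(f"trace length {I.size} must exceed window {window}")
    n_out = I.size - window
    views = np.lib.stride_tricks.sliding_window_view(I, w)[:n_out]
    mean = views.sum(axis=1) / window
    sd = np.sqrt(((views - views.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / window)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd > 0, mean / sd, np.nan)
    valid = np.isfinite(snr)
    mean_snr = float(np.mean(snr[valid])) if valid.any() else float("nan")
    return RollingSNR(
        window=window,
        rolling_mean=mean,
        rolling_sd=sd,
        snr=snr,
        mean_snr=mean_snr,
        n_zero_sd=int(np.count_nonzero(~valid)),
    )


# -- correlation reports --------------------------------------------------

#: |rho| cut-points and labels; boundaries belong to the higher bin.
_RHO_BINS = (0.1, 0.4, 0.7, 0.89)
_RHO_LABELS = ("negligible", "weak", "moderate", "strong", "very strong")


def categorize_rho(rho: float) -> str:
    """Effect-size label for a Spearman coefficient.

    |rho| < 0.1 negligible, 0.1-0.39 weak, 0.4-0.69 moderate, 0.7-0.89
    strong, > 0.89 very strong; a value exactly on 0.1/0.4/0.7 joins the
    higher bin, exactly 0.89 is still "strong".
    """
    a = abs(float(rho))
    if not 0.0 <= a <= 1.0 + 1e-12:
        raise ValueError("|rho| must lie in [0, 1]")
    if a < _RHO_BINS[0]:
        return _RHO_LABELS[0]
    if a < _RHO_BINS[1]:
        return _RHO_LABELS[1]
    if a < _RHO_BINS[2]:
        return _RHO_LABELS[2]
    if a <= _RHO_BINS[3]:
        return _RHO_LABELS[3]
    return _RHO_LABELS[4]


@dataclass
class CorrelationReport:
    rho: float
    p_value: float
    category: str
    n: int

    def to_dict(self) -> dict:
        return {
            "rho": float(self.rho),
            "p_value": float(self.p_value),
            "category": self.category,
            "n": int(self.n),
        }


def _spearman_report(x, y) -> CorrelationReport:
    rho, p = stats.spearmanr(x, y)
    return CorrelationReport(
        rho=float(rho), p_value=float(p), category=categorize_rho(rho), n=len(x)
    )


def velocity_snr_correlation(
    series: SyncedSeries, window: int = 20, inclusive_window: bool = False
) -> CorrelationReport:
    """Spearman correlation between frame velocity and rolling SNR.

    Each SNR window is paired with the velocity at its first frame;
    windows with undefined SNR are dropped.  Refuses fewer than 10 pairs.
    """
    snr = rolling_snr(series["intensity"], window, inclusive_window)
    velocity = series["velocity"][: snr.snr.size]
    valid = np.isfinite(snr.snr)
    pairs = int(np.count_nonzero(valid))
    if pairs < 10:
        raise ValueError(f"only {pairs} velocity-SNR pairs; need >= 10")
    return _spearman_report(velocity[valid], snr.snr[valid])


def angular_residual_analysis(series: SyncedSeries, fit: CurveFit) -> CorrelationReport:
    """Spearman correlation between scope angle and distance-corrected residual.

    The residual is the displayed intensity minus the fitted curve's
    prediction at the frame's distance, removing the dominant distance
    effect before probing for an angular one.  Flat systems use their
    fitted line as the prediction.
    """
    residual = series["intensity"] - fit.predict(series["distance"])
    angle = series["angle"]
    if residual.size < 10:
        raise ValueError("need >= 10 frames for the angular residual analysis")
    return _spearman_report(angle, residual)


# -- CPR zone statistics --------------------------------------------------


@dataclass
class ZoneReport:
    """Zone-wise intensity statistics and significance tests."""

    zone_means: dict[int, float]  # g.u., over the window's zone-mean frames
    zone_sds: dict[int, float]
    shapiro_p: dict[int, float]
    kruskal_stat: float
    kruskal_p: float
    pairwise_p: dict[tuple[int, int], float]  # Bonferroni-corrected
    n_frames: int
    method: str = "ranksum"
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "zone_means_gu": {str(z): v for z, v in self.zone_means.items()},
            "zone_sds_gu": {str(z): v for z, v in self.zone_sds.items()},
            "shapiro_p": {str(z): v for z, v in self.shapiro_p.items()},
            "kruskal_stat": self.kruskal_stat,
            "kruskal_p": self.kruskal_p,
            "pairwise_p": {f"{a}v{b}": v for (a, b), v in self.pairwise_p.items()},
            "n_frames": self.n_frames,
            "method": self.method,
            "warnings": self.warnings,
        }


def _dunn_pairwise(samples: dict[int, np.ndarray]) -> dict[tuple[int, int], float]:
    """Dunn's z-tests on pooled ranks with tie correction (uncorrected p)."""
    zones = sorted(samples)
    pooled = np.concatenate([samples[z] for z in zones])
    ranks = stats.rankdata(pooled)
    N = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for z in zones:
        n = samples[z].size
        mean_ranks[z] = ranks[start : start + n].mean()
        sizes[z] = n
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    out = {}
    for a, b in combinations(zones, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        zstat = (mean_ranks[a] - mean_ranks[b]) / se
        out[(a, b)] = 2.0 * stats.norm.sf(abs(zstat))
    return out


def zone_cpr_analysis(
    traces: list[IntensityTrace],
    window_s: float = 1.0,
    method: str = "ranksum",
) -> ZoneReport:
    """Center-versus-periphery comparison of the 12 zoned wells.

    For each zone the four well traces are averaged frame-by-frame over
    the first ``window_s`` seconds; the resulting per-frame zone means are
    the samples.  Shapiro-Wilk normality is recorded per zone; zones are
    compared with Kruskal-Wallis regardless (the pipeline's omnibus for
    non-normal display data), followed by three pairwise tests (rank-sum by
    default, Dunn's via ``method="dunn"``) with Bonferroni correction x3.
    """
    if method not in ("ranksum", "dunn"):
        raise ValueError("method must be 'ranksum' or 'dunn'")
    by_zone: dict[int, list[IntensityTrace]] = {}
    for tr in traces:
        if tr.zone is None:
            raise ValueError(f"trace {tr.roi_id!r} has no zone label")
        by_zone.setdefault(tr.zone, []).append(tr)
    if sorted(by_zone) != [1, 2, 3] or any(len(v) != 4 for v in by_zone.values()):
        raise ValueError("need exactly 4 traces in each of zones 1, 2, 3")

    warnings: list[str] = []
    lengths = [
        int(np.count_nonzero(tr.t - tr.t[0] < window_s)) for tr in traces
    ]
    n_frames = min(lengths)
    if len(set(lengths)) > 1:
        warnings.append("unequal_trace_lengths_trimmed")
    fps = traces[0].fps
    if n_frames < fps * window_s * 0.5:
        raise ValueError(f"only {n_frames} frames inside the {window_s} s window")

    # sort by ROI id so well ordering cannot affect float summation order
    samples = {
        z: np.mean(
            [tr.intensity[:n_frames] for tr in sorted(trs, key=lambda x: x.roi_id)],
            axis=0,
        )
        for z, trs in by_zone.items()
    }
    zone_means = {z: float(np.mean(s)) for z, s in samples.items()}
    zone_sds = {z: float(np.std(s, ddof=1)) for z, s in samples.items()}
    shapiro_p = {}
    for z, s in samples.items():
        if np.ptp(s) == 0:
            shapiro_p[z] = float("nan")
            warnings.append(f"zone{z}_constant")
        else:
            shapiro_p[z] = float(stats.shapiro(s).pvalue)

    try:
        kw = stats.kruskal(*(samples[z] for z in sorted(samples)))
        kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)
    except ValueError:  # all values identical across zones
        kw_stat, kw_p = 0.0, 1.0

    pairwise: dict[tuple[int, int], float] = {}
    if method == "dunn":
        raw = _dunn_pairwise(samples)
    else:
        raw = {}
        for a, b in combinations(sorted(samples), 2):
            if np.ptp(np.concatenate([samples[a], samples[b]])) == 0:
                raw[(a, b)] = 1.0
            else:
                raw[(a, b)] = float(stats.ranksums(samples[a], samples[b]).pvalue)
    for pair, p in raw.items():
        pairwise[pair] = float(min(1.0, 3.0 * p))

    return ZoneReport(
        zone_means=zone_means,
        zone_sds=zone_sds,
        shapiro_p=shapiro_p,
        kruskal_stat=kw_stat,
        kruskal_p=kw_p,
        pairwise_p=pairwise,
        n_frames=n_frames,
        method=method,
        warnings=warnings,
    )


# -- ideal optical distance ----------------------------------------------


def iod_empirical(distance_mm, fully_visible) -> float:
    """Minimum distance (mm) at which the full target was visible."""
    d = np.asarray(distance_mm, dtype=float)
    vis = np.asarray(fully_visible, dtype=bool)
    if d.size != vis.size:
        raise ValueError("distance and visibility flags must align")
    if not vis.any():
        raise IODNotReachedError("target never fully visible: IOD not reached")
    return float(np.min(d[vis]))


def iod_geometric(half_fov_deg: float, target_half_extent_mm: float) -> float:
    """Closed-form IOD of an ideal pinhole: ``half_extent / tan(half_fov)``."""
    if not 0.0 < half_fov_deg < 90.0:
        raise ValueError("half_fov_deg must lie in (0, 90)")
    if target_half_extent_mm <= 0:
        raise ValueError("target_half_extent_mm must be positive")
    return target_half_extent_mm / np.tan(np.radians(half_fov_deg))
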