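# Methods

`nirchar` characterizes how a clinical near-infrared (NIR) fluorescence
camera system's *displayed* signal depends on camera positioning. The
pipeline mirrors a bench protocol: a well-plate phantom filled with an
ICG-albumin solution is imaged while an electromagnetic tracker streams
the scope-tip pose; the two recordings are aligned post hoc, the
distance-intensity relationship is fitted, and working-distance
recommendations and screen-uniformity statistics are derived. Because no
public recordings of such bench sessions exist, the package ships a
synthetic generator that reproduces the statistical structure of the
protocol, so every downstream stage is exercised and tested end to end.

## Response models

Displayed intensity I (grayscale units, g.u., 0–255) versus
camera-target distance x (mm) is modeled by one of three families:

* **inverse-square** — `I(x) = A/(x − C)² + B`. A (g.u.·mm²) sets the
  source strength, C (mm) the pole offset (constrained below the data
  range), B (g.u.) the far-field floor. Typical of uncompensated
  laparoscopes.
* **sigmoid** — `I(x) = A/(1 + exp(B(x − C))) + D` with B > 0 (1/mm), so
  the high plateau A + D sits at short distance; C (mm) is the center, D
  (g.u.) the far floor. Observed on one laparoscopic system when moving
  toward the target.
* **flat** — `I(x) = a·x + b` with |a| ≈ 0: distance-compensated display
  electronics. Such systems vary over only a few g.u. across the whole
  working range (the reference value used throughout is a 4.23 g.u.
  band).

One system class shows *hysteresis*: sigmoid response while approaching
the target and inverse-square while retreating. The pipeline therefore
splits frames by the sign of a smoothed distance derivative (centered
0.5 s moving average; |derivative| < 2 mm/s counts as static) before
fitting such systems.

## Ideal fluorescence distance (IFD)

The IFD balances two failure modes: too close risks saturation and steep
intensity-vs-distance gradients; too far costs signal-to-noise. Three
constructions are implemented:

* **double line** (inverse-square responses): fit `y = max(a·x + b,
  c·x + d)` by exhaustive breakpoint search over the distance-sorted
  points (each side ≥ 3 points; per-segment least squares; candidates
  scored by the residual sum of squares of the max-composite over all
  points; ties resolve to the smaller breakpoint). The IFD is the line
  intersection `(d − b)/(a − c)`. The O(n²) search is deterministic and
  directly checkable against a brute-force oracle.
* **sigmoid transition**: the zero of the sigmoid's third derivative on
  the near side, `IFD = C − ln(2 + √3)/B`. The constant
  `ln(2 + √3) = 1.316958…` is the exact value of the conventionally
  quoted 1.317; at this distance the curve sits at `(3 + √3)/6 = 78.87%`
  ("79%") of its total range — past the saturation-prone plateau, before
  the steep region.
* **sigmoid alternative**: the mirrored far-side threshold
  `C + 1.317/B` (21% of range). Reported but considered inferior because
  it lies in the low-intensity tail.

The fitters use `scipy.optimize.curve_fit` (trust-region reflective,
parameter/residual tolerances 1e-8, ≤ 10⁴ evaluations) from several
heuristic starts, keeping the best converged solution by residual sum of
squares. Sigmoid orientation (B > 0, A ≥ 0) is enforced by bounds rather
than post-hoc sign flips. Frames at the display cap are excluded from
fitting by default (the saturated plateau otherwise distorts the pole
region). R² is `1 − SS_res/SS_tot`; a constant signal (SS_tot = 0) is
reported as R² undefined with a `constant_signal` flag.

**Family classification** (`select_family`) first smooths the intensity
with a 21-frame moving average and classifies the series as flat when
the robust (0.5–99.5 percentile) smoothed range stays within the
4.23 g.u. band — raw best-R² selection is ill-posed when all families
fit noise equally. Otherwise inverse-square and sigmoid compete by R²,
with one guard: a sigmoid whose fitted center lies outside the observed
distance span shows no plateau evidence (it is mimicking a monotone
decay with an extra parameter) and cannot win.

## Synchronization

The tracker (40 fps) and the video quantifier (22–30 fps) run on
independent clocks. A deliberate physical tap of the scope leaves a
simultaneous artifact in both streams; the synthetic generator injects a
single-sample ~15 mm positional spike in the pose track and a 3-frame
×0.25 dim in the trace. Detection is a robust z-score (scaled MAD,
threshold 6) of the stream's first difference, with three practical
refinements: the difference is detrended by a centered ~0.5 s rolling
median (steady hand motion shifts the local difference level without
being an artifact); trace detection runs on `log1p(intensity)` so the
multiplicative dim is equally visible at any signal level; and anomalous
steps within 0.18 s are clustered, returning the onset sample, so the
spike and the dim map to the same instant. A manual tap time always
bypasses detection.

Pose timestamps are shifted by the tap-time difference; distance and
angle are linearly interpolated at each video frame time; frames outside
the shifted pose span are dropped, never extrapolated, and frames within
±0.2 s of the tap are masked so the artifact does not enter the
analysis. Per-frame velocity is `|Δdistance|/Δt`.

## Signal metrics

* **Rolling SNR**: forward windows of 20 frames; window mean divided by
  the window's population standard deviation (divisor 20); the series
  yields N − 20 windows and the mean SNR averages the windows with
  positive SD (zero-SD windows — constant or saturated signal — are
  excluded and counted). A 21-frame variant with divisor 20 is available
  behind `inclusive_window=True` for comparison with conventions that
  write the window bounds inclusively.
* **Correlations**: Spearman's ρ with the conventional effect-size bins
  |ρ| < 0.1 negligible, < 0.4 weak, < 0.7 moderate, ≤ 0.89 strong,
  > 0.89 very strong (boundaries join the higher bin). Velocity is
  paired with the SNR window starting at that frame. Angular effects are
  probed on the *residual* (intensity minus the fitted curve's
  prediction at the frame's distance), removing the dominant distance
  effect first; flat systems use their fitted line as the prediction.
* **Center vs periphery (CPR)**: the twelve zoned wells (zone 1 the four
  innermost, zone 2 diagonally outward, zone 3 the plate corners) are
  traced for 1 s at the IOD; the four wells of each zone are averaged
  frame-by-frame and the per-frame zone means are compared:
  Shapiro–Wilk recorded per zone, Kruskal–Wallis omnibus regardless of
  normality, and three pairwise tests (Wilcoxon rank-sum by default,
  Dunn's z-tests on pooled ranks via `method="dunn"`) with ×3 Bonferroni
  correction.
* **Ideal optical distance (IOD)**: minimum distance at which the full
  plate is visible. Closed form for the pinhole model,
  `half_extent/tan(half FOV)` with the plate half-diagonal (106.07 mm)
  as the half extent; the empirical variant takes the minimum distance
  among frames whose full-visibility flag is set (from rendered frames).

## Synthetic generator

The generator defines the study conditions; its defaults are fixed:

* **Plate**: 150 mm square, 6×6 wells of 20 mm diameter, 5 mm depth.
* **Tracked volume**: 120–600 mm vertically; waypoints outside are
  rejected.
* **Motion regimes**: `static_episodic` dwells 4 s at set distances
  (140–440 mm in 60 mm steps, out and back so both directions occur)
  with 100 mm/s transits; `slow` sweeps 140–440 mm continuously at
  20 mm/s; `fast` at 170 mm/s; ~40–60 s per recording. Pose noise
  defaults to 0.3 mm; the scope wobbles a few mm laterally and ±6°
  around perpendicular.
* **Presets**: four built-ins spanning the observed behaviors —
  `pnl_like` (inverse-square laparoscope, centrally bright), `eml_like`
  (hysteresis laparoscope, strongest central brightening), `emo_like`
  (flat arm-mounted open system, slightly peripheral-bright),
  `sso_like` (inverse-square handheld open system, mid-zone bright).
  Their numeric parameters are calibrated so outputs land on the
  published scale (peak intensities ~74–230 g.u.; flat range within
  4.23 g.u.) inside the tracked volume; the source coefficients of real
  systems are not public.
* **Vignette**: `g(r) = 1 − k·r^p` (central-bright), `1 − k·(1 − r)^p`
  (peripheral-bright), `1 − k·|2r − 1|^p` (mid-bright), with r the
  screen radius as a fraction of the plate half-diagonal under a
  perpendicular pinhole view. Only zone means are published for real
  systems; the functional form is a modeling choice.
* **Signal chain**: law value × vignette factor, clipped to
  [0, 255], plus additive Gaussian sensor noise (σ 1.5–3 g.u.), clipped
  again. 8-bit saturation is a hard cap at 255.

What the generator does **not** emulate: fluorophore photophysics
(photobleaching, quenching), angled-lens (30°) viewing geometry, rolling
shutter or gain dynamics, ROI tracking errors on moving video, and any
genuine angular dependence of the displayed signal (angle wobble is
generated but does not modulate intensity — which is what makes the
angular-residual null tests meaningful). Passing tests therefore
demonstrate that the *analysis* recovers planted structure under
realistic noise, not that real systems behave like the presets.

## Numerical and design choices

* All randomness flows from `numpy.random.default_rng` seeds; identical
  seeds give bit-identical outputs, and report JSON is written with
  sorted keys so full runs are byte-reproducible.
* Distances are mm internally; timestamps are seconds from recording
  start.
* Interpolation never extrapolates; dropped-frame counts are recorded in
  the series provenance.
* The double-line breakpoint search warns `single_regime` when the best
  split sits at the minimum segment size (data likely one line), and
  refuses parallel segments.
* Zone traces are sorted by ROI id before averaging so well ordering
  cannot perturb float summation.
* Problem sizes in the test suite and acceptance script (≤ 60 s
  recordings, 500-point fits, 20-seed Monte-Carlo checks) keep a full
  run to a few minutes while leaving the statistical checks
  well-powered.

## Limitations

Real recordings would add ROI-tracking noise, exposure/gain adaptation,
and scene-dependent background that the generator omits; fitted
coefficients of the built-in presets are calibration choices, not
measurements of the named device classes; and the IOD here is specific
to the 15 cm plate — smaller clinical targets shrink it proportionally.
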