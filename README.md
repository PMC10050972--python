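# nirchar

Characterization of clinical near-infrared (NIR) fluorescence camera
systems: how the *displayed* indocyanine-green (ICG) signal depends on
camera–target distance, motion, angulation, and screen position.

Surgeons and algorithm developers read perfusion off the grayscale NIR
feed, but different camera systems map the same scene to very different
displayed intensities: some follow an inverse-square distance falloff,
one shows a direction-dependent sigmoid (hysteresis), and
distance-compensated open systems stay flat within a few grayscale
units. The same systems also brighten either the screen center or the
periphery. `nirchar` implements the full quantification pipeline for
bench characterization of such systems — and, since no raw recordings
of this kind are publicly deposited, a synthetic camera/tracker
simulator that reproduces the protocol's statistical structure so the
whole pipeline is testable end to end.

## What it computes

Displayed intensity *I* (g.u.) versus distance *x* (mm) is fitted with

* inverse-square `I = A/(x − C)² + B`,
* sigmoid `I = A/(1 + e^{B(x − C)}) + D` (B > 0), or
* a flat line for distance-compensated systems,

choosing the family by goodness of fit (R²). From the fits come the
**ideal fluorescence distance (IFD)** — close enough for signal-to-noise,
far enough to avoid saturation:

* double-line breakpoint `IFD = (d − b)/(a − c)` of the piecewise fit
  `y = max(ax + b, cx + d)` for inverse-square responses;
* sigmoid third-derivative threshold `IFD = C − 1.317/B` (the curve at
  79% of its range), with the far-side alternative `C + 1.317/B`.

The pipeline also synchronizes the electromagnetic-tracker pose stream
(40 fps) with the video-rate intensity trace on a deliberate tap
artifact, computes a 20-frame rolling SNR and its Spearman correlation
with movement velocity, probes angular effects on distance-corrected
residuals, finds the **ideal optical distance (IOD)** (minimum distance
showing the whole 15 × 15 cm field), and tests the **center-versus-
periphery relationship (CPR)** across three diagonal well zones
(Kruskal–Wallis + Bonferroni pairwise).

## Worked example

Characterize the hysteresis-type laparoscope preset across all three
motion regimes:

```sh
nirchar run --preset eml_like --seed 20230329 --out results/run
```

(the numbered scripts under `analysis/` run the same stages one at a
time, with their own fixed seeds). The command prints:

```
System characterization — preset eml_like (seed 20230329)

regime             mean vel  mean SNR peak (g.u.)   @ (mm)  IOD (mm)    rho(res,angle)
static_episodic       19.43      17.5        53.6    140.5     183.7               N/A
                 IFD: 129.9 mm (sigmoid_transition), 193.9 mm (sigmoid_alternative), 214.6 mm (double_line)
                 velocity-SNR Spearman rho = -0.280 (weak, p = 1.27e-17, n = 895)
slow                  20.03       9.9        52.8    140.0     183.7               N/A
                 IFD: 125.4 mm (sigmoid_transition), 192.3 mm (sigmoid_alternative), 219.7 mm (double_line)
                 velocity-SNR Spearman rho = -0.007 (negligible, p = 0.789, n = 1291)
fast                 166.68       3.2        51.1    150.4     183.7               N/A
                 IFD: 117.9 mm (sigmoid_transition), 180.9 mm (sigmoid_alternative), 229.8 mm (double_line)
```

Reading it: the scope was moved at ~20 mm/s in the static/episodic and
slow regimes and ~167 mm/s in the fast one; faster movement degrades the
rolling SNR (17.5 → 3.2). Because this system is direction-dependent,
frames are split by motion direction: the approach frames fit a sigmoid
whose third-derivative threshold puts the IFD at ~125-130 mm, while the
retreat frames fit an inverse-square law whose double-line breakpoint
sits at ~215-230 mm. The zone table for the same run shows the central
brightening typical of laparoscopes — zone means 23.2, 20.2 and
14.6 g.u. from center to periphery, all pairwise differences significant
(p < 0.001 after Bonferroni correction) — so identical wells look
dimmer at the screen edge, a bias an operator should know about.

The flat open-system preset behaves oppositely:

```sh
nirchar run --preset emo_like --regime static --seed 20230329 --out results/emo
```

reports family `linear`, no IFD, a systematic intensity range of
3.78 g.u. across a 300 mm distance sweep, and a *brighter* periphery
(zone 3 at 225.0 g.u. versus zone 1 at 223.2 g.u.), i.e. built-in
compensation that defeats the usual falloff.

## Library layout

| module | contents |
| --- | --- |
| `nirchar.geometry` | well-plate phantom, zone layout |
| `nirchar.presets` | camera response presets, motion profiles |
| `nirchar.simulate` | pose tracks, intensity traces, rendered frames |
| `nirchar.io` | CSV/JSON/PNG readers and writers |
| `nirchar.sync` | tap detection, clock alignment, direction split |
| `nirchar.curves` | model fits, double-line and sigmoid IFD |
| `nirchar.metrics` | rolling SNR, correlations, CPR statistics, IOD |
| `nirchar.pipeline` / `nirchar.cli` | end-to-end runs and the `nirchar` command |

The numbered scripts under `analysis/` run the same stages one at a
time, writing intermediates under `results/`.

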