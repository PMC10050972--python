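"""Fit distance-intensity laws and extract the IFD for every recording.

Hysteresis systems are split by motion direction (sigmoid on approach,
inverse-square on retreat) before fitting; all other systems are
classified by response family (flat / inverse-square / sigmoid).  The IFD
comes from the double-line breakpoint for inverse-square responses and
from the sigmoid third-derivative threshold for sigmoid responses.
Writes one JSON per recording under results/03_fits/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))
from analysis.common import OUT_ROOT, REGIMES_FOR  # noqa: E402

from nirchar.io import read_synced_csv, write_json
from nirchar.pipeline import analyze_series
from nirchar.presets import get_preset

synced_dir = OUT_ROOT / "02_synced"
out = OUT_ROOT / "03_fits"

for preset_name, regimes in REGIMES_FOR.items():
    preset = get_preset(preset_name)
    for regime in regimes:
        series = read_synced_csv(synced_dir / f"synced_{preset_name}_{regime}.csv")
        entry = analyze_series(preset, series)
        write_json(entry, out / f"analysis_{preset_name}_{regime}.json")
        ifds = ", ".join(
            f"{x['ifd_mm']:.1f} mm ({x['method']})" for x in entry["ifd"]
        ) or "none (flat response)"
        print(f"{preset_name:>9} {regime:<16} family={entry['family']:<36} IFD: {ifds}")

print(f"\nfit reports written to {out}")
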