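"""Align the pose and video clocks of every simulated recording.

Detects the tap artifact independently in the pose stream (positional
spike) and in the zone-1 mean intensity trace (transient dim), shifts the
pose clock by the difference, interpolates distance and angle onto the
video timebase, and writes one synced series per recording under
results/02_synced/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))
from analysis.common import OUT_ROOT, REGIMES_FOR  # noqa: E402

from nirchar.io import read_pose_csv, read_traces_csv, write_synced_csv
from nirchar.pipeline import mean_trace
from nirchar.sync import synchronize

raw = OUT_ROOT / "01_raw"
out = OUT_ROOT / "02_synced"

for preset_name, regimes in REGIMES_FOR.items():
    for regime in regimes:
        track = read_pose_csv(raw / f"pose_{preset_name}_{regime}.csv")
        traces = read_traces_csv(raw / f"traces_{preset_name}_{regime}.csv")
        series = synchronize(mean_trace(traces, roi_id="zone1_mean"), track)
        write_synced_csv(series, out / f"synced_{preset_name}_{regime}.csv")
        p = series.provenance
        print(
            f"{preset_name:>9} {regime:<16} taps: trace {p['tap_trace_s']:.3f} s / "
            f"pose {p['tap_track_s']:.3f} s -> shift {p['shift_s']:+.3f} s, "
            f"{len(series)} frames retained"
        )

print(f"\nsynced series written to {out}")
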