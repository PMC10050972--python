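"""Simulate bench recordings for every camera preset and motion regime.

Writes the tracker pose stream (40 fps) and the four zone-1 ROI intensity
traces (video rate) for each preset x regime as CSV under results/01_raw/.
Open systems are only assessed with episodic static movement, mirroring
their clinical use on a fixed or handheld mount.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))
from analysis.common import OUT_ROOT, REGIMES_FOR, SEED, stage_seed  # noqa: E402

from nirchar.io import write_pose_csv, write_traces_csv
from nirchar.pipeline import simulate_recording
from nirchar.presets import BUILTIN_PRESETS

out = OUT_ROOT / "01_raw"

for preset_name, preset in BUILTIN_PRESETS.items():
    for ri, regime in enumerate(REGIMES_FOR[preset_name]):
        track, traces = simulate_recording(
            preset, regime, seed=stage_seed(preset_name, ri, 0)
        )
        write_pose_csv(track, out / f"pose_{preset_name}_{regime}.csv")
        write_traces_csv(traces, out / f"traces_{preset_name}_{regime}.csv")
        print(
            f"{preset_name:>9} {regime:<16} {len(track):>5} pose samples, "
            f"{len(traces[0])} video frames x {len(traces)} ROIs "
            f"({track.duration:.1f} s)"
        )

print(f"\nraw recordings written to {out} (seed {SEED})")
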