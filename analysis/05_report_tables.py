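"""Assemble the per-system characterization tables from the stage outputs.

Combines the fit/metric reports (stage 03) and the optics/CPR reports
(stage 04) into one text table pair per system — distance-intensity
behavior per regime, and zone statistics at the IOD — under
results/05_report/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))
from analysis.common import OUT_ROOT, REGIMES_FOR, SEED  # noqa: E402

from nirchar.pipeline import table2_text, table3_text

fits_dir = OUT_ROOT / "03_fits"
optics_dir = OUT_ROOT / "04_optics"
out = OUT_ROOT / "05_report"
out.mkdir(parents=True, exist_ok=True)

for preset_name, regimes in REGIMES_FOR.items():
    optics = json.loads((optics_dir / f"{preset_name}.json").read_text())
    report = {
        "preset": preset_name,
        "seed": SEED,
        "iod_geometric_mm": optics["iod_geometric_mm"],
        "cpr": optics["cpr"],
        "regimes": {
            regime: json.loads(
                (fits_dir / f"analysis_{preset_name}_{regime}.json").read_text()
            )
            for regime in regimes
        },
    }
    t2, t3 = table2_text(report), table3_text(report)
    (out / f"table2_{preset_name}.txt").write_text(t2)
    (out / f"table3_{preset_name}.txt").write_text(t3)
    print(t2)
    print(t3)

print(f"report tables written to {out}")
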