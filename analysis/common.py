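"""Shared constants for the numbered analysis scripts."""

from pathlib import Path

SEED = 20230329
OUT_ROOT = Path(__file__).resolve().parents[1] / "results"

#: study regimes per system: laparoscopes are moved continuously as well,
#: open systems only statically with episodic repositioning
REGIMES_FOR = {
    "pnl_like": ("static_episodic", "slow", "fast"),
    "eml_like": ("static_episodic", "slow", "fast"),
    "emo_like": ("static_episodic",),
    "sso_like": ("static_episodic",),
}

_PRESET_INDEX = {name: i for i, name in enumerate(REGIMES_FOR)}


def stage_seed(preset_name: str, regime_idx: int, stage: int) -> int:
    base = SEED + 100_000 * _PRESET_INDEX[preset_name]
    return (base * 7919 + regime_idx * 101 + stage) % 2**31
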