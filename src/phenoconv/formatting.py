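"""Single home for the printed-number conventions: percentages to one
decimal, percent increases to the nearest integer, ratios to one decimal."""

from __future__ import annotations

__all__ = ["pct1", "pct_int", "ratio1"]


def pct1(x: float) -> str:
    return f"{x:.1f}%"


def pct_int(x: float) -> str:
    return f"{round(x):d}%"


def ratio1(x: float) -> str:
    return f"{x:.1f}"
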