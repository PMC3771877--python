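"""Reporting helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for printed figures,
    unlike Python's banker's rounding)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale
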