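"""Rounding and median conventions used across all reported metrics.

All printed ratios and percentages in the comparison tables follow
round-half-away-from-zero (the convention of spreadsheet software), not
Python's default round-half-to-even. Medians over an even number of
conditions are the arithmetic mean of the two central order statistics.
"""

from __future__ import annotations

import math
from typing import Sequence


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round to `decimals` places, ties away from zero (spreadsheet style)."""
    if math.isnan(x):
        return x
    factor = 10.0**decimals
    scaled = x * factor
    # nudge by a relative epsilon so values like 2.675*100 = 267.49999999
    # still round up as a human (or spreadsheet) would
    eps = math.copysign(1e-9, scaled) * max(1.0, abs(scaled))
    rounded = math.floor(abs(scaled + eps) + 0.5) * math.copysign(1.0, scaled)
    return rounded / factor


def round_ratio(x: float) -> float:
    """One-decimal ratio as printed in the comparison tables."""
    return round_half_away(x, 1)


def round_percent(x: float) -> int:
    """Whole-number percent as printed in the comparison tables."""
    return int(round_half_away(x, 0))


def round_minutes(x: float) -> int:
    """Nearest whole minute, half away from zero."""
    return int(round_half_away(x, 0))


def median(values: Sequence[float]) -> float:
    """Median; even counts average the two central order statistics."""
    if not values:
        raise ValueError("median of empty sequence")
    s = sorted(values)
    n = len(s)
    mid = n // 2
    if n % 2:
        return float(s[mid])
    return (s[mid - 1] + s[mid]) / 2.0
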