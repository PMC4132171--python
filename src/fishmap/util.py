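"""Small shared numeric helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_up", "percent_of"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero-half upward."""
    return int(math.floor(x + 0.5))


def percent_of(part: float, whole: float) -> int:
    """Whole-number percentage, rounded half up (e.g. 43.9/919 -> 5)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round_half_up(100.0 * part / whole)
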