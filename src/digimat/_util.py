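"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as report tables conventionally do.

    Python's built-in ``round`` uses banker's rounding, which would print
    e.g. 59.65 as 59.6; health-report tables round 5 up.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits``."""
    if denominator == 0:
        raise ValueError("percentage undefined for a zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def is_missing(value) -> bool:
    """True for None and NaN; numeric zero is a value, not missingness."""
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False
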