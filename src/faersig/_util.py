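"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, digits: int = 2) -> float:
    """Round with ties away from zero at `digits` decimals (display convention).

    Python's builtin round() is banker's rounding; published pharmacovigilance
    tables conventionally round half up, and the printed percentages this
    package reproduces require it (e.g. 4.545 -> 4.55, not 4.54).
    """
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, digits: int = 2) -> float:
    """count / total expressed in percent, half-up rounded; 0.0 when total == 0."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, digits)
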