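"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used in all reported
    percentages), unlike Python's banker's rounding."""
    quantum = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(d)
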