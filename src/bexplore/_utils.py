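"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def percent(count: int, total: int, decimals: int) -> float:
    """100 * count/total rounded half-up to ``decimals`` places.

    Computed in exact decimal arithmetic so boundary ties (e.g. 0.575%)
    round predictably upward rather than by float/banker's rounding.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        quantum, rounding=ROUND_HALF_UP)
    return float(value)
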