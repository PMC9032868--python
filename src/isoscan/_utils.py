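"""Shared numeric helpers: exact half-up decimal rounding for report fields."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round a float half-up (0.005 -> 0.01 at 2 digits), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """100*count/total with exact decimal half-up rounding.

    Computed in decimal arithmetic from the integers so values sitting on a
    rounding boundary (e.g. 7/9 at 2 digits) never drift through binary
    floats.
    """
    if total <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count:
        raise ValueError("count must be non-negative")
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )
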