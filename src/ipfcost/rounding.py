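"""Display rounding helpers.

All internal arithmetic runs on unrounded floats; rounding happens only at
the reporting boundary, half-up (ties away from zero, so 94.5 % -> 95 %),
matching how the reference tables were printed.  ``round_half_up`` goes
through ``Decimal`` to avoid binary-float surprises such as
``round(2.675, 2) == 2.67``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "round_half_up_int"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up_int(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(round_half_up(x, 0))
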