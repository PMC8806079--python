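"""Display-layer rounding.

Coefficients are reported to 3-4 decimals and percentages to 1 decimal.
Rounding goes through ``decimal`` with half-up on the shortest decimal
representation, so 0.04855 -> 0.0486 regardless of binary float artifacts;
raw precision is preserved everywhere upstream.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def display_round(x: float, ndigits: int) -> float:
    """Round half-up on the decimal representation of ``x``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
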