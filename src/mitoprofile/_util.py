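"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties away from zero.

    Report-time rounding convention: 0.0005 -> 0.001, -0.0005 -> -0.001.
    Internal arithmetic elsewhere stays at full precision.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
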