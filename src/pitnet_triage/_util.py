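"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (half-up), as clinical tables do.

    Python's built-in ``round`` uses banker's rounding, which would turn
    e.g. 4.75 into 4.7; reported percentages and averages here follow the
    half-up convention instead (4.75 -> 4.8).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
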