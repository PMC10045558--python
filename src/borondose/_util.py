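"""Small shared numerical helpers."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as in the reported tables.

    Python's built-in ``round`` uses banker's rounding; report tables use
    conventional half-up rounding (2.75 -> 2.8).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
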