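"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(value, ndigits: int = 2) -> float:
    """Round half-up to ``ndigits`` decimals (0.005 -> 0.01, not banker's).

    Accepts ints, floats and Fractions.  Ratios should be passed as
    Fractions when exact decimal arithmetic matters (percentage tables).
    """
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def ratio_pct(count: int, total: int, ndigits: int = 2) -> float:
    """Exact ``100 * count / total`` rounded half-up to ``ndigits``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(Fraction(100 * count, total), ndigits)
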