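"""Shared numeric helpers: half-up rounding and clean decimal rendering."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(value: float | Fraction | Decimal, ndigits: int) -> Decimal:
    """Round to ``ndigits`` decimals with ties away from zero (half-up).

    Python's builtin ``round`` is banker's rounding; printed survey
    percentages such as 16/19 -> 84.2 follow the half-up convention, so all
    user-facing rounding goes through here.
    """
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    elif isinstance(value, Decimal):
        dec = value
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    return dec.quantize(quantum, rounding=ROUND_HALF_UP)


def fmt_decimal(value: Decimal | float) -> str:
    """Render a number without floating artefacts or trailing zeros.

    ``Decimal("2.5")`` -> ``"2.5"``, ``Decimal("5.0")`` -> ``"5"``,
    ``8.5`` -> ``"8.5"``.
    """
    if not isinstance(value, Decimal):
        value = Decimal(repr(float(value)))
    text = format(value.normalize(), "f")
    return text
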