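"""Shared numeric helpers.

All printed percentages and ratios in this package use round-half-up
(commercial rounding), matching the conventions of the report tables the
pipeline emulates. Python's built-in round() is banker's rounding and is
deliberately not used for any user-visible figure.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction


def round_half_up(x: float | Decimal | Fraction, ndigits: int) -> float:
    """Round to ``ndigits`` decimals, ties away from zero."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    elif isinstance(x, Decimal):
        d = x
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Exact integer-ratio percentage, rounded half-up.

    Uses Decimal division so values such as 4000/79 -> 50.63 are free of
    binary floating-point artifacts.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    d = (Decimal(numerator) * 100) / Decimal(denominator)
    return round_half_up(d, ndigits)


def mean_sd(values, ndigits: int | None = None) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    The mean is accumulated in Decimal so that decimal inputs (e.g. nm
    measurements quoted to one decimal) average exactly; the sd uses a
    float sqrt. With ndigits set, both are rounded half-up.
    """
    vals = [Decimal(repr(float(v))) for v in values]
    n = len(vals)
    if n < 2:
        raise ValueError("need at least two values for a sample sd")
    mean = sum(vals) / n
    ss = sum((v - mean) ** 2 for v in vals)
    sd = Decimal(float(ss / (n - 1)) ** 0.5)
    if ndigits is None:
        return float(mean), float(sd)
    return round_half_up(mean, ndigits), round_half_up(sd, ndigits)
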