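"""Half-up decimal rounding for report output.

Python's builtin ``round`` uses banker's rounding; the published rule
tables round half away from zero (e.g. a lift of exactly 1.1875 prints
as 1.19, and a support of 29.5454...% prints as 29.55).  Metrics are
ratios of integer counts, so rounding from an exact :class:`~fractions.Fraction`
avoids any binary-float artefact at the half-way point.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(value: float | Fraction, ndigits: int = 2) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def fmt_percent(frac: Fraction, ndigits: int = 2) -> str:
    """Format a fraction as a percentage string, half-up rounded."""
    return f"{round_half_up(frac * 100, ndigits):.{ndigits}f}"


def fmt_pvalue(p: float, floor: float = 0.001) -> str:
    """Render a p-value to 4 significant figures, with a '<floor' form."""
    if p < floor:
        return f"<{floor}"
    return f"{p:.4g}"
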