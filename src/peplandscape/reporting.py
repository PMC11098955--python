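"""Percentage presentation helpers.

All pipeline statistics are computed in full precision; only at reporting
time are they reduced to the printed precision. Two conventions are used:

* ``format_percent`` — a single ratio, rounded half-even at the requested
  number of decimals (banker's rounding on the exact decimal expansion,
  not on a float).
* ``percent_split`` — a multi-class split of one total, where the largest
  class is presented as the complement of the rounded smaller classes so
  the printed percentages always sum to exactly 100. This is the usual
  convention for pie-chart-style class breakdowns.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal
from typing import Sequence


def format_percent(numerator: int | float, denominator: int | float, decimals: int = 1) -> float:
    """Exact percentage of ``numerator / denominator`` rounded half-even.

    Returns a float carrying exactly ``decimals`` significant decimal
    places (e.g. ``format_percent(2282, 4522, 1) == 50.5``).

    Raises ``ZeroDivisionError`` if the denominator is zero: an undefined
    coverage must be reported as missing upstream, never silently as 0%.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(str(numerator)) * 100 / Decimal(str(denominator))).quantize(
        quantum, rounding=ROUND_HALF_EVEN
    )
    return float(value)


def percent_split(counts: Sequence[int], decimals: int = 1) -> list[float]:
    """Percentages for a class split that sum to exactly 100.

    Every class except the largest is rounded half-even at ``decimals``;
    the largest class is the complement ``100 - sum(others)``, absorbing
    the rounding residue. Ties for largest go to the first occurrence.
    """
    total = sum(counts)
    if total == 0:
        raise ZeroDivisionError("percentage split undefined for empty total")
    if not counts:
        return []
    largest = max(range(len(counts)), key=lambda i: counts[i])
    out: list[float] = []
    for i, c in enumerate(counts):
        if i == largest:
            out.append(0.0)  # placeholder, filled below
        else:
            out.append(format_percent(c, total, decimals))
    quantum = Decimal(1).scaleb(-decimals)
    residue = Decimal(100) - sum(Decimal(str(v)) for i, v in enumerate(out) if i != largest)
    out[largest] = float(residue.quantize(quantum))
    return out
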