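"""Small data-preparation helpers used before scoring."""

from __future__ import annotations

from typing import Sequence

from .errors import InputError

__all__ = ["median_affected"]


def median_affected(per_sector_counts: Sequence[float], rule: str = "lower") -> float:
    """Median of per-sector affected/in-need counts for one country.

    UN appeals sometimes report the number of people affected per
    intervention sector (health, food security, ...) rather than overall;
    because sectors overlap, summing overstates the total, so a median of
    the sector counts is used as the single input figure.

    For an even number of sectors the default ``rule="lower"`` takes the
    lower of the two central values — appeal figures are whole-person
    counts and interpolation would invent a fractional count.
    ``rule="interpolate"`` averages the central pair instead.
    """
    if len(per_sector_counts) == 0:
        raise InputError("median_affected needs at least one sector count")
    if rule not in ("lower", "interpolate"):
        raise InputError(f"rule must be 'lower' or 'interpolate', got {rule!r}")
    ordered = sorted(per_sector_counts)
    n = len(ordered)
    if n % 2 == 1:
        return ordered[n // 2]
    lo, hi = ordered[n // 2 - 1], ordered[n // 2]
    return lo if rule == "lower" else (lo + hi) / 2
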