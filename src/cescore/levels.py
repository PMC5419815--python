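"""The three-level ordinal severity scale and its numeric weights.

Every indicator value is classified onto this scale; the scale is totally
ordered (low/medium < high < extreme) and each level carries a fixed weight
(0.5, 1.0, 1.5) used by the additive dimension sums.
"""

from __future__ import annotations

import enum
import functools

__all__ = ["SeverityLevel", "level_weight"]


@functools.total_ordering
class SeverityLevel(enum.Enum):
    """Ordinal severity level of a single indicator.

    The order low/medium < high < extreme is the substantive ordering used
    everywhere (monotonicity of scores, colour scales); comparisons between
    levels use it directly.
    """

    LOW_MEDIUM = "low_medium"
    HIGH = "high"
    EXTREME = "extreme"

    @property
    def rank(self) -> int:
        """Position on the ordinal scale: 0, 1 or 2."""
        return _RANKS[self]

    @property
    def weight(self) -> float:
        """Numeric scoring weight: 0.5, 1.0 or 1.5."""
        return _WEIGHTS[self]

    @classmethod
    def from_label(cls, label: str) -> "SeverityLevel":
        """Parse a textual label such as ``"extreme"`` (case-insensitive)."""
        try:
            return cls(label.strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown severity level {label!r}; expected one of: {valid}") from None

    def __lt__(self, other: object) -> bool:
        if not isinstance(other, SeverityLevel):
            return NotImplemented
        return self.rank < other.rank

    def __str__(self) -> str:  # used verbatim in CSV output
        return self.value


_RANKS = {
    SeverityLevel.LOW_MEDIUM: 0,
    SeverityLevel.HIGH: 1,
    SeverityLevel.EXTREME: 2,
}

_WEIGHTS = {
    SeverityLevel.LOW_MEDIUM: 0.5,
    SeverityLevel.HIGH: 1.0,
    SeverityLevel.EXTREME: 1.5,
}


def level_weight(level: SeverityLevel) -> float:
    """Return the scoring weight of *level* (0.5 / 1.0 / 1.5)."""
    if not isinstance(level, SeverityLevel):
        raise TypeError(f"expected SeverityLevel, got {type(level).__name__}")
    return level.weight
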