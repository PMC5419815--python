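"""Core scoring engine: classification, dimension sums, severity and need.

The model scores one country at one assessment date from eight indicator
values — four describing vulnerability (pre-existing susceptibility of the
population) and four describing exposure (the crisis footprint). Each raw
value is classified onto the three-level ordinal scale via per-indicator
cut-offs, levels are mapped to weights 0.5/1.0/1.5, weights are summed per
dimension (each sum in [2, 6]) and the two sums are multiplied:

    severity = vulnerability_sum * exposure_sum          in [4, 36]
    need     = severity * people_in_need_millions        >= 0

Missing indicator values propagate under the default strict policy (the
severity score is then unresolved); alternatively they can be imputed at a
configured level — typically "extreme", the assumption a scorer makes when
an indicator is unobtainable precisely because the situation is dire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .config import ModelConfig
from .errors import ConfigError, InputError
from .levels import SeverityLevel, level_weight

__all__ = [
    "MissingPolicy",
    "CountryYearRecord",
    "ScoredCountry",
    "classify_indicator",
    "dimension_sum",
    "severity_score",
    "need_score",
    "score_country",
    "score_panel",
]

#: Attainable range of a dimension sum (4 indicators x weight 0.5..1.5).
DIMENSION_SUM_RANGE = (2.0, 6.0)
#: Attainable range of the severity score.
SEVERITY_RANGE = (4.0, 36.0)


@dataclass(frozen=True)
class MissingPolicy:
    """How unresolved (na) indicator levels are handled.

    mode
        ``"strict"``  — any missing level leaves the dimension sum, and hence
        the severity score, unresolved.
        ``"impute_extreme"`` — missing levels are scored as extreme.
        ``"impute_level"`` — missing levels are scored as ``impute_as``.
    """

    mode: str = "strict"
    impute_as: Optional[SeverityLevel] = None

    _MODES = ("strict", "impute_extreme", "impute_level")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ConfigError(f"missing policy mode must be one of {self._MODES}, got {self.mode!r}")
        if self.mode == "impute_level" and not isinstance(self.impute_as, SeverityLevel):
            raise ConfigError("impute_level requires impute_as to be a SeverityLevel")
        if self.mode != "impute_level" and self.impute_as is not None:
            raise ConfigError("impute_as is only meaningful with mode='impute_level'")

    @property
    def imputation_level(self) -> Optional[SeverityLevel]:
        """The level substituted for a missing one, or None under strict."""
        if self.mode == "strict":
            return None
        if self.mode == "impute_extreme":
            return SeverityLevel.EXTREME
        return self.impute_as

    @classmethod
    def strict(cls) -> "MissingPolicy":
        return cls("strict")

    @classmethod
    def impute_extreme(cls) -> "MissingPolicy":
        return cls("impute_extreme")

    @classmethod
    def impute(cls, level: SeverityLevel) -> "MissingPolicy":
        return cls("impute_level", impute_as=level)


@dataclass(frozen=True)
class CountryYearRecord:
    """Raw indicator values for one country at one assessment date.

    ``values`` maps indicator name to a raw value in native units; a missing
    (na) value is ``None``.  ``people_in_need_millions`` is the need-score
    multiplier and may itself be missing.
    """

    country: str
    assessment_date: str
    values: Mapping[str, Optional[float]]
    population: Optional[float] = None
    people_in_need_millions: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.country:
            raise InputError("record is missing a country name")
        pin = self.people_in_need_millions
        if pin is not None:
            if not math.isfinite(pin):
                raise InputError(f"{self.country}: people_in_need_millions is not finite")
            if pin < 0:
                raise InputError(f"{self.country}: people_in_need_millions must be >= 0, got {pin}")


@dataclass(frozen=True)
class ScoredCountry:
    """Scoring output for one country-year.

    ``levels`` keeps the classified level per indicator — ``None`` where the
    raw value was na, even when the score imputed it (the heat map shows na
    cells blank; imputation affects only the sums and is recorded in
    ``imputed_indicators``).
    """

    country: str
    assessment_date: str
    levels: Mapping[str, Optional[SeverityLevel]]
    vulnerability_sum: Optional[float]
    exposure_sum: Optional[float]
    severity_score: Optional[float]
    need_score: Optional[float]
    people_in_need_millions: Optional[float] = None
    imputed_indicators: tuple[str, ...] = ()
    missing_indicators: tuple[str, ...] = ()


def classify_indicator(
    value: Optional[float], definition
) -> Optional[SeverityLevel]:
    """Classify one raw indicator value onto the three-level scale.

    ``None`` (na) propagates to ``None``. A value exactly at a cut-off is
    assigned the severer level, in both directions.
    """
    if value is None:
        return None
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise InputError(
            f"indicator {definition.name!r}: value {value!r} is not numeric"
        ) from None
    if math.isnan(value):
        return None
    if not math.isfinite(value):
        raise InputError(f"indicator {definition.name!r}: non-finite value {value!r}")
    if definition.direction == "higher_is_worse":
        if value >= definition.cutoff_hi:
            return SeverityLevel.EXTREME
        if value >= definition.cutoff_lo:
            return SeverityLevel.HIGH
        return SeverityLevel.LOW_MEDIUM
    # lower_is_worse: cutoff_hi < cutoff_lo
    if value <= definition.cutoff_hi:
        return SeverityLevel.EXTREME
    if value <= definition.cutoff_lo:
        return SeverityLevel.HIGH
    return SeverityLevel.LOW_MEDIUM


def dimension_sum(
    levels: Sequence[Optional[SeverityLevel]], policy: MissingPolicy = MissingPolicy()
) -> Optional[float]:
    """Sum the four weights of one dimension, applying the missing policy.

    Returns ``None`` when a level is missing under the strict policy;
    otherwise a value in [2, 6].
    """
    if len(levels) != 4:
        raise InputError(f"a dimension has exactly 4 indicator slots, got {len(levels)}")
    substitute = policy.imputation_level
    total = 0.0
    for lv in levels:
        if lv is None:
            if substitute is None:
                return None
            lv = substitute
        total += level_weight(lv)
    return total


def severity_score(vulnerability_sum: float, exposure_sum: float) -> float:
    """Severity = vulnerability_sum x exposure_sum, in [4, 36]."""
    lo, hi = DIMENSION_SUM_RANGE
    for label, s in (("vulnerability_sum", vulnerability_sum), ("exposure_sum", exposure_sum)):
        if not (lo <= s <= hi):
            raise InputError(f"{label} must lie in [{lo}, {hi}], got {s}")
    return vulnerability_sum * exposure_sum


def need_score(severity: float, people_in_need_millions: float) -> float:
    """Level of need = severity x millions of people in need."""
    lo, hi = SEVERITY_RANGE
    if not (lo <= severity <= hi):
        raise InputError(f"severity must lie in [{lo}, {hi}], got {severity}")
    if people_in_need_millions < 0:
        raise InputError(f"people_in_need_millions must be >= 0, got {people_in_need_millions}")
    return severity * people_in_need_millions


def score_country(
    record: CountryYearRecord,
    config: ModelConfig,
    policy: MissingPolicy = MissingPolicy(),
) -> ScoredCountry:
    """Score one country-year record end to end.

    Classifies every configured indicator, sums the two dimensions under the
    missing policy, multiplies them into the severity score and multiplies
    by people in need for the need score.  All missingness and imputation is
    recorded on the result.
    """
    unknown = sorted(set(record.values) - set(config.names))
    if unknown:
        raise ConfigError(
            f"{record.country}: unknown indicator name(s): {', '.join(unknown)}"
        )

    levels: dict[str, Optional[SeverityLevel]] = {}
    for defn in config:
        levels[defn.name] = classify_indicator(record.values.get(defn.name), defn)

    missing = tuple(name for name, lv in levels.items() if lv is None)
    imputed = missing if policy.imputation_level is not None else ()

    v_sum = dimension_sum([levels[d.name] for d in config.vulnerability], policy)
    e_sum = dimension_sum([levels[d.name] for d in config.exposure], policy)

    severity = severity_score(v_sum, e_sum) if v_sum is not None and e_sum is not None else None
    pin = record.people_in_need_millions
    need = need_score(severity, pin) if severity is not None and pin is not None else None

    return ScoredCountry(
        country=record.country,
        assessment_date=record.assessment_date,
        levels=levels,
        vulnerability_sum=v_sum,
        exposure_sum=e_sum,
        severity_score=severity,
        need_score=need,
        people_in_need_millions=pin,
        imputed_indicators=imputed,
        missing_indicators=missing,
    )


def score_panel(
    records: Sequence[CountryYearRecord],
    config: ModelConfig,
    policy: MissingPolicy = MissingPolicy(),
) -> list[ScoredCountry]:
    """Score a whole panel of country-year records."""
    return [score_country(r, config, policy) for r in records]
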