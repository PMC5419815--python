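"""Model configuration: indicator definitions and their cut-offs.

A valid configuration holds exactly four vulnerability and four exposure
indicators. Each indicator carries two cut-offs in its native units that
split its range into the three severity levels. Cut-offs are deliberately
*data*, not code: they ship as an editable YAML file so users can audit and
replace them without touching the engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError
from .levels import SeverityLevel

__all__ = [
    "IndicatorDefinition",
    "ModelConfig",
    "load_config",
    "default_config",
    "DIMENSIONS",
    "DIRECTIONS",
]

DIMENSIONS = ("vulnerability", "exposure")
DIRECTIONS = ("higher_is_worse", "lower_is_worse")

#: Number of indicators required per dimension.
INDICATORS_PER_DIMENSION = 4


@dataclass(frozen=True)
class IndicatorDefinition:
    """One indicator's identity, dimension, direction and cut-offs.

    Parameters
    ----------
    name
        Unique identifier, also the CSV column name.
    dimension
        ``"vulnerability"`` or ``"exposure"``.
    direction
        ``"higher_is_worse"`` if larger raw values mean a worse situation
        (e.g. % children underweight), ``"lower_is_worse"`` if smaller raw
        values do (e.g. GNI per capita, adult literacy).
    cutoff_lo
        Boundary between low/medium and high, in native units.
    cutoff_hi
        Boundary between high and extreme, in native units.  For a
        ``lower_is_worse`` indicator ``cutoff_hi < cutoff_lo``.
    units
        Free-text unit label, informational only.
    """

    name: str
    dimension: str
    direction: str
    cutoff_lo: float
    cutoff_hi: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ConfigError("indicator name must be a non-empty string")
        if self.dimension not in DIMENSIONS:
            raise ConfigError(
                f"indicator {self.name!r}: dimension must be one of {DIMENSIONS}, "
                f"got {self.dimension!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ConfigError(
                f"indicator {self.name!r}: direction must be one of {DIRECTIONS}, "
                f"got {self.direction!r}"
            )
        for field in ("cutoff_lo", "cutoff_hi"):
            v = getattr(self, field)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
                raise ConfigError(f"indicator {self.name!r}: {field} must be a finite number")
        if self.direction == "higher_is_worse" and not self.cutoff_lo < self.cutoff_hi:
            raise ConfigError(
                f"indicator {self.name!r}: higher_is_worse requires cutoff_lo < cutoff_hi "
                f"(got {self.cutoff_lo} >= {self.cutoff_hi})"
            )
        if self.direction == "lower_is_worse" and not self.cutoff_lo > self.cutoff_hi:
            raise ConfigError(
                f"indicator {self.name!r}: lower_is_worse requires cutoff_lo > cutoff_hi "
                f"(got {self.cutoff_lo} <= {self.cutoff_hi})"
            )

    def level_interval(self, level: SeverityLevel) -> tuple[float, float]:
        """Half-open/closed raw-value interval that classifies to *level*.

        Returned as ``(a, b)`` with ``a < b``; used by the synthetic-data
        generator to draw values inside a target level.  The interval beyond
        the extreme cut-off is bounded by one cut-off span.
        """
        span = abs(self.cutoff_hi - self.cutoff_lo)
        if self.direction == "higher_is_worse":
            return {
                SeverityLevel.LOW_MEDIUM: (self.cutoff_lo - span, self.cutoff_lo),
                SeverityLevel.HIGH: (self.cutoff_lo, self.cutoff_hi),
                SeverityLevel.EXTREME: (self.cutoff_hi, self.cutoff_hi + span),
            }[level]
        return {
            SeverityLevel.LOW_MEDIUM: (self.cutoff_lo, self.cutoff_lo + span),
            SeverityLevel.HIGH: (self.cutoff_hi, self.cutoff_lo),
            SeverityLevel.EXTREME: (self.cutoff_hi - span, self.cutoff_hi),
        }[level]


class ModelConfig:
    """An ordered collection of exactly 4 + 4 indicator definitions.

    Iteration order is vulnerability block first, then exposure block, each
    in the order given — this order is also the heat-map column order.
    """

    def __init__(self, indicators: Iterable[IndicatorDefinition]) -> None:
        indicators = tuple(indicators)
        names = [d.name for d in indicators]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ConfigError(f"duplicate indicator names: {', '.join(dupes)}")
        vuln = tuple(d for d in indicators if d.dimension == "vulnerability")
        expo = tuple(d for d in indicators if d.dimension == "exposure")
        if len(vuln) != INDICATORS_PER_DIMENSION or len(expo) != INDICATORS_PER_DIMENSION:
            raise ConfigError(
                "a model configuration needs exactly "
                f"{INDICATORS_PER_DIMENSION} vulnerability and "
                f"{INDICATORS_PER_DIMENSION} exposure indicators "
                f"(got {len(vuln)} and {len(expo)})"
            )
        self.vulnerability: tuple[IndicatorDefinition, ...] = vuln
        self.exposure: tuple[IndicatorDefinition, ...] = expo

    @property
    def indicators(self) -> tuple[IndicatorDefinition, ...]:
        return self.vulnerability + self.exposure

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.indicators)

    def __iter__(self):
        return iter(self.indicators)

    def __len__(self) -> int:
        return len(self.indicators)

    def __getitem__(self, name: str) -> IndicatorDefinition:
        for d in self.indicators:
            if d.name == name:
                return d
        raise KeyError(name)

    def __repr__(self) -> str:
        return f"ModelConfig({', '.join(self.names)})"


_REQUIRED_KEYS = {"name", "dimension", "direction", "cutoff_lo", "cutoff_hi"}
_OPTIONAL_KEYS = {"units"}


def _parse_block(i: int, block: object) -> IndicatorDefinition:
    if not isinstance(block, Mapping):
        raise ConfigError(f"indicator entry #{i + 1} is not a mapping")
    keys = set(block)
    missing = _REQUIRED_KEYS - keys
    if missing:
        raise ConfigError(
            f"indicator entry #{i + 1}: missing required field(s) {', '.join(sorted(missing))}"
        )
    unknown = keys - _REQUIRED_KEYS - _OPTIONAL_KEYS
    if unknown:
        raise ConfigError(
            f"indicator entry #{i + 1}: unknown field(s) {', '.join(sorted(unknown))}"
        )
    return IndicatorDefinition(**{k: block[k] for k in keys})


def config_from_mapping(doc: Mapping) -> ModelConfig:
    """Build a :class:`ModelConfig` from a parsed YAML/JSON document."""
    if not isinstance(doc, Mapping) or "indicators" not in doc:
        raise ConfigError("configuration document must be a mapping with an 'indicators' list")
    blocks = doc["indicators"]
    if not isinstance(blocks, Sequence) or isinstance(blocks, (str, bytes)):
        raise ConfigError("'indicators' must be a list of indicator blocks")
    return ModelConfig(_parse_block(i, b) for i, b in enumerate(blocks))


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from a YAML or JSON file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read configuration file {path}: {exc}") from exc
    try:
        if path.suffix.lower() == ".json":
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse configuration file {path}: {exc}") from exc
    return config_from_mapping(doc)


def default_config() -> ModelConfig:
    """The packaged default configuration with provisional cut-offs.

    The cut-off values are documented provisional defaults (see the methods
    note); any real assessment should review and, where needed, override
    them via a user-supplied YAML file.
    """
    text = resources.files("cescore").joinpath("data/default_config.yaml").read_text()
    return config_from_mapping(yaml.safe_load(text))
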