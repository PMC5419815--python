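"""CSV input/output for panels, scored results and mortality tables.

Panel CSV: one row per country-year with columns ``country``, ``date``, one
column per configured indicator, plus optional ``population`` and
``people_in_need_millions``. An empty cell is na.

Scored CSV output is deterministic: rows sorted by (country, date), scores
formatted to two decimals, lists semicolon-joined — re-running the scoring
on the same inputs yields a byte-identical file.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import ModelConfig
from .errors import ConfigError, InputError
from .scoring import CountryYearRecord, ScoredCountry
from .validation import ExcessMortalityRecord

__all__ = [
    "read_panel",
    "write_panel",
    "scored_to_frame",
    "write_scored",
    "read_mortality",
    "write_mortality",
]

_PANEL_META_COLUMNS = ("country", "date", "population", "people_in_need_millions")
MORTALITY_COLUMNS = ("context", "excess_mortality_per_100k_year")


def _cell(value) -> Optional[float]:
    """A CSV cell as float, with empty/NaN -> None."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def read_panel(path: str | Path, config: ModelConfig) -> list[CountryYearRecord]:
    """Read a country-year panel CSV into records.

    Unknown columns raise :class:`ConfigError`; an indicator column that is
    absent altogether is treated as na for every row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"country": str, "date": str})
    except OSError as exc:
        raise InputError(f"cannot read panel file {path}: {exc}") from exc
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"malformed panel CSV {path}: {exc}") from exc

    known = set(_PANEL_META_COLUMNS) | set(config.names)
    unknown = sorted(set(df.columns) - known)
    if unknown:
        raise ConfigError(
            f"panel {path.name}: unknown column(s) not in the model configuration: "
            f"{', '.join(unknown)}"
        )
    for required in ("country", "date"):
        if required not in df.columns:
            raise InputError(f"panel {path.name}: missing required column {required!r}")

    records = []
    for i, row in df.iterrows():
        country = row["country"]
        if not isinstance(country, str) or not country.strip():
            raise InputError(f"panel {path.name}: row {i + 2}: empty country name")
        try:
            values = {
                name: _cell(row[name]) for name in config.names if name in df.columns
            }
            records.append(
                CountryYearRecord(
                    country=country.strip(),
                    assessment_date=str(row["date"]).strip(),
                    values=values,
                    population=_cell(row.get("population")),
                    people_in_need_millions=_cell(row.get("people_in_need_millions")),
                )
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"panel {path.name}: row {i + 2}: {exc}") from exc
    return records


def write_panel(
    records: Sequence[CountryYearRecord], path: str | Path, config: ModelConfig
) -> None:
    """Write records to the panel CSV dialect consumed by :func:`read_panel`."""
    rows = []
    for r in records:
        row: dict = {"country": r.country, "date": r.assessment_date}
        for name in config.names:
            row[name] = r.values.get(name)
        row["population"] = r.population
        row["people_in_need_millions"] = r.people_in_need_millions
        rows.append(row)
    cols = ["country", "date", *config.names, "population", "people_in_need_millions"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.2f}"


def scored_to_frame(scored: Sequence[ScoredCountry], config: ModelConfig) -> pd.DataFrame:
    """Tabulate scored records: levels as text, scores to two decimals.

    Rows are sorted by (country, date) so output is order-independent.
    """
    if not scored:
        raise InputError("no scored records to tabulate")
    rows = []
    for s in sorted(scored, key=lambda s: (s.country, s.assessment_date)):
        row: dict = {"country": s.country, "date": s.assessment_date}
        for name in config.names:
            lv = s.levels.get(name)
            row[f"{name}_level"] = "" if lv is None else str(lv)
        row["vulnerability_sum"] = _fmt(s.vulnerability_sum)
        row["exposure_sum"] = _fmt(s.exposure_sum)
        row["severity_score"] = _fmt(s.severity_score)
        row["need_score"] = _fmt(s.need_score)
        row["people_in_need_millions"] = _fmt(s.people_in_need_millions)
        row["imputed_indicators"] = ";".join(s.imputed_indicators)
        row["missing_indicators"] = ";".join(s.missing_indicators)
        rows.append(row)
    return pd.DataFrame(rows)


def write_scored(
    scored: Sequence[ScoredCountry], path: str | Path, config: ModelConfig
) -> None:
    """Write the scored CSV (deterministic ordering and float formatting)."""
    scored_to_frame(scored, config).to_csv(path, index=False)


def read_mortality(path: str | Path) -> list[ExcessMortalityRecord]:
    """Read an excess-mortality CSV (columns: context, excess_mortality_per_100k_year)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"context": str})
    except OSError as exc:
        raise InputError(f"cannot read mortality file {path}: {exc}") from exc
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"malformed mortality CSV {path}: {exc}") from exc
    missing = [c for c in MORTALITY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"mortality {path.name}: missing column(s): {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ExcessMortalityRecord(
                    context=str(row["context"]).strip(),
                    excess_mortality_rate=float(row["excess_mortality_per_100k_year"]),
                )
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"mortality {path.name}: row {i + 2}: {exc}") from exc
    return records


def write_mortality(records: Sequence[ExcessMortalityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.context, r.excess_mortality_rate) for r in records],
        columns=list(MORTALITY_COLUMNS),
    ).to_csv(path, index=False)
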