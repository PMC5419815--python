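"""Heat maps and score bar charts with the three-colour severity semantics.

Colour semantics are fixed across all figures: yellow = low/medium, orange
= high, red = extreme; a missing indicator cell is left blank.  Score bar
charts bin the continuous scores with half-open bins assigning a boundary
value to the severer colour — severity: yellow < 10 <= orange < 20 <= red;
need: yellow < 50 <= orange < 150 <= red.

Heat-map cells take their colour from the *classified level stored on the
scored record*, never recomputed from raw values, so the figure and the
score always agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from html import escape
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import to_rgb
from matplotlib.patches import Patch

from .errors import InputError
from .levels import SeverityLevel
from .scoring import ScoredCountry

__all__ = ["ColorRule", "render_heatmap", "render_score_bars", "heatmap_html"]

logger = logging.getLogger(__name__)

YELLOW = "#FFD700"
ORANGE = "#FF8C00"
RED = "#CC0000"
BLANK = "#FFFFFF"


@dataclass(frozen=True)
class ColorRule:
    """Maps levels or scores onto the yellow/orange/red palette.

    ``bins`` holds the two thresholds for score scales (ignored for the
    indicator-level scale); ``score >= bins[1]`` is red, ``>= bins[0]``
    orange, below yellow.
    """

    scale: str  # {indicator_level, severity_bins, need_bins}
    bins: tuple[float, float] = (0.0, 0.0)
    colors: tuple[str, str, str] = (YELLOW, ORANGE, RED)
    missing_color: str = BLANK

    @classmethod
    def indicator_level(cls) -> "ColorRule":
        return cls(scale="indicator_level")

    @classmethod
    def severity_bins(cls) -> "ColorRule":
        return cls(scale="severity_bins", bins=(10.0, 20.0))

    @classmethod
    def need_bins(cls) -> "ColorRule":
        return cls(scale="need_bins", bins=(50.0, 150.0))

    def color_for_level(self, level: Optional[SeverityLevel]) -> str:
        """Colour of one ordinal level; missing -> blank."""
        if level is None:
            return self.missing_color
        return self.colors[level.rank]

    def color_for_score(self, score: float) -> str:
        """Colour of one numeric score under the half-open bins (total map)."""
        if score >= self.bins[1]:
            return self.colors[2]
        if score >= self.bins[0]:
            return self.colors[1]
        return self.colors[0]


def _panel_layout(
    scored: Sequence[ScoredCountry], sort_key=None
) -> tuple[list[str], list[str], list[str]]:
    """(dates, countries, indicator names) with deterministic ordering."""
    if not scored:
        raise InputError("cannot render an empty panel")
    dates = sorted({s.assessment_date for s in scored})
    countries = sorted({s.country for s in scored}, key=sort_key)
    indicators = list(scored[0].levels)
    for s in scored:
        if list(s.levels) != indicators:
            raise InputError(
                f"{s.country} {s.assessment_date}: inconsistent indicator set in panel"
            )
    return dates, countries, indicators


def render_heatmap(
    scored: Sequence[ScoredCountry],
    rule: Optional[ColorRule] = None,
    sort_key=None,
    title: str = "Indicator severity heat map",
) -> plt.Figure:
    """Render the country x indicator heat map, one panel per year.

    Rows are countries (alphabetical unless *sort_key* orders them),
    columns are the eight indicators (vulnerability block then exposure
    block, in configuration order), and each assessment date gets its own
    aligned panel sharing the row order.  Missing cells are blank.
    """
    rule = rule or ColorRule.indicator_level()
    dates, countries, indicators = _panel_layout(scored, sort_key)
    lookup = {(s.country, s.assessment_date): s for s in scored}

    n_rows, n_cols = len(countries), len(indicators)
    fig_w = max(4.0, 0.45 * n_cols * len(dates) + 1.8)
    fig_h = max(2.5, 0.32 * n_rows + 1.4)
    fig, axes = plt.subplots(1, len(dates), figsize=(fig_w, fig_h), squeeze=False)

    for ax, date in zip(axes[0], dates):
        rgb = [[to_rgb(rule.missing_color)] * n_cols for _ in range(n_rows)]
        for i, country in enumerate(countries):
            rec = lookup.get((country, date))
            if rec is None:
                continue
            for j, name in enumerate(indicators):
                rgb[i][j] = to_rgb(rule.color_for_level(rec.levels[name]))
        ax.imshow(rgb, aspect="auto", interpolation="nearest")
        ax.set_xticks(range(n_cols))
        ax.set_xticklabels(indicators, rotation=90, fontsize=7)
        ax.set_yticks(range(n_rows))
        ax.set_yticklabels(countries if ax is axes[0][0] else [""] * n_rows, fontsize=7)
        ax.set_title(str(date), fontsize=9)
        # thin grid so blank (missing) cells remain visible
        ax.set_xticks([x - 0.5 for x in range(1, n_cols)], minor=True)
        ax.set_yticks([y - 0.5 for y in range(1, n_rows)], minor=True)
        ax.grid(which="minor", color="#DDDDDD", linewidth=0.5)
        ax.tick_params(which="both", length=0)

    fig.suptitle(title, fontsize=11)
    fig.legend(
        handles=[
            Patch(facecolor=YELLOW, label="low/medium"),
            Patch(facecolor=ORANGE, label="high"),
            Patch(facecolor=RED, label="extreme"),
            Patch(facecolor=BLANK, edgecolor="#999999", label="not available"),
        ],
        loc="lower center",
        ncol=4,
        fontsize=7,
        frameon=False,
    )
    fig.tight_layout(rect=(0, 0.06, 1, 0.97))
    return fig


def render_score_bars(
    scored: Sequence[ScoredCountry],
    which: str = "severity",
    rule: Optional[ColorRule] = None,
    sort_key=None,
) -> plt.Figure:
    """Render one coloured bar per country for severity or need scores.

    Bar height is the score; bar colour follows the bin rule.  Countries
    whose score is unresolved are omitted with a logged notice.
    """
    if which not in ("severity", "need"):
        raise InputError(f"which must be 'severity' or 'need', got {which!r}")
    rule = rule or (ColorRule.severity_bins() if which == "severity" else ColorRule.need_bins())
    if not scored:
        raise InputError("cannot render an empty panel")

    attr = "severity_score" if which == "severity" else "need_score"
    resolved, skipped = [], []
    for s in sorted(scored, key=sort_key or (lambda s: s.country)):
        score = getattr(s, attr)
        (resolved if score is not None else skipped).append((s.country, score))
    for country, _ in skipped:
        logger.info("omitting %s from %s bars: score unresolved", country, which)

    fig, ax = plt.subplots(figsize=(max(4.0, 0.5 * len(resolved) + 1.5), 4.0))
    if resolved:
        names = [c for c, _ in resolved]
        vals = [v for _, v in resolved]
        ax.bar(names, vals, color=[rule.color_for_score(v) for v in vals], edgecolor="#555555")
        ax.set_xticks(range(len(names)))
        ax.set_xticklabels(names, rotation=90, fontsize=7)
    ax.set_ylabel("severity score" if which == "severity" else "need score")
    lo, hi = rule.bins
    ax.set_title(
        f"{which.capitalize()} score "
        f"(yellow < {lo:g} ≤ orange < {hi:g} ≤ red)",
        fontsize=10,
    )
    fig.tight_layout()
    return fig


def heatmap_html(
    scored: Sequence[ScoredCountry],
    rule: Optional[ColorRule] = None,
    sort_key=None,
) -> str:
    """Standalone HTML table variant of the heat map (one table per year)."""
    rule = rule or ColorRule.indicator_level()
    dates, countries, indicators = _panel_layout(scored, sort_key)
    lookup = {(s.country, s.assessment_date): s for s in scored}

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<style>table{border-collapse:collapse;margin:1em 0}"
        "td,th{border:1px solid #ccc;padding:3px 6px;font:12px sans-serif}"
        "td.cell{width:2em;height:1.2em}</style>",
        "<title>Indicator severity heat map</title></head><body>",
    ]
    for date in dates:
        parts.append(f"<h2>{escape(str(date))}</h2><table><tr><th>country</th>")
        parts.extend(f"<th>{escape(n)}</th>" for n in indicators)
        parts.append("</tr>")
        for country in countries:
            parts.append(f"<tr><th>{escape(country)}</th>")
            rec = lookup.get((country, date))
            for name in indicators:
                level = rec.levels[name] if rec is not None else None
                color = rule.color_for_level(level)
                label = "" if level is None else str(level)
                parts.append(f"<td class='cell' style='background:{color}' title='{label}'></td>")
            parts.append("</tr>")
        parts.append("</table>")
    parts.append("</body></html>")
    return "".join(parts)
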