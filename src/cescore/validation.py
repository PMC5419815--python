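"""Reliability assessment: severity scores versus excess mortality.

Excess mortality (direct + indirect deaths per 100,000 per year above the
pre-crisis baseline) is an accepted, if late and noisy, measure of how bad
a complex emergency really was.  A useful severity score should *order*
emergencies the way excess mortality does.  This module quantifies that
agreement two ways:

* Spearman's rank correlation between severity score and mortality rate;
* a rank-window concordance: a context is *concordant* when its severity
  rank and its mortality rank differ by at most ``window`` positions
  (default 1, average ranks for ties).  This operationalizes the visual
  judgement "the score follows mortality" into a reproducible count and
  names the discordant contexts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = ["ExcessMortalityRecord", "ValidationResult", "compare_with_mortality"]


@dataclass(frozen=True)
class ExcessMortalityRecord:
    """Excess mortality for one emergency context (country + period)."""

    context: str
    excess_mortality_rate: float  # deaths per 100,000 persons per year

    def __post_init__(self) -> None:
        if not self.context:
            raise InputError("mortality record is missing a context name")
        if not math.isfinite(self.excess_mortality_rate):
            raise InputError(f"{self.context}: excess mortality rate is not finite")
        if self.excess_mortality_rate < 0:
            raise InputError(
                f"{self.context}: excess mortality rate must be >= 0, "
                f"got {self.excess_mortality_rate}"
            )


@dataclass(frozen=True)
class ValidationResult:
    """Summary of the severity-vs-mortality rank agreement."""

    n_contexts: int
    rank_correlation: float  # Spearman's rho
    n_concordant: int
    discordant_contexts: tuple[str, ...]
    window: int

    def summary(self) -> str:
        lines = [
            f"contexts compared : {self.n_contexts}",
            f"Spearman's rho    : {self.rank_correlation:.3f}",
            f"concordant (|rank diff| <= {self.window}) : "
            f"{self.n_concordant} of {self.n_contexts}",
        ]
        if self.discordant_contexts:
            lines.append("discordant        : " + ", ".join(self.discordant_contexts))
        return "\n".join(lines)


def compare_with_mortality(
    scored: Sequence[tuple[str, float]],
    mortality: Sequence[ExcessMortalityRecord],
    window: int = 1,
) -> ValidationResult:
    """Compare severity scores with excess mortality across contexts.

    Parameters
    ----------
    scored
        ``(context, severity_score)`` pairs.
    mortality
        One :class:`ExcessMortalityRecord` per context; the context sets
        must match exactly (records are joined by name).
    window
        Maximum |severity rank - mortality rank| for a context to count as
        concordant.

    The result is independent of input row order: contexts are aligned by
    name and processed in sorted order.
    """
    if window < 0:
        raise InputError(f"window must be >= 0, got {window}")
    sev = {c: s for c, s in scored}
    if len(sev) != len(scored):
        raise InputError("duplicate context names in severity input")
    mort = {m.context: m.excess_mortality_rate for m in mortality}
    if len(mort) != len(mortality):
        raise InputError("duplicate context names in mortality input")
    only_sev = sorted(set(sev) - set(mort))
    only_mort = sorted(set(mort) - set(sev))
    if only_sev or only_mort:
        parts = []
        if only_sev:
            parts.append("missing mortality for: " + ", ".join(only_sev))
        if only_mort:
            parts.append("missing severity for: " + ", ".join(only_mort))
        raise InputError("unmatched contexts — " + "; ".join(parts))
    n = len(sev)
    if n < 3:
        raise InputError(f"need at least 3 matched contexts, got {n}")

    contexts = sorted(sev)
    s = np.array([float(sev[c]) for c in contexts])
    m = np.array([float(mort[c]) for c in contexts])
    if not (np.isfinite(s).all() and np.isfinite(m).all()):
        raise InputError("non-finite severity or mortality value")

    if (s == s[0]).all() or (m == m[0]).all():
        # a constant series has no defined rho; all-tied vs all-tied is
        # reported as full agreement, constant vs varying as no signal
        rho = 1.0 if (s == s[0]).all() and (m == m[0]).all() else 0.0
    else:
        rho = float(stats.spearmanr(s, m).statistic)

    rank_s = stats.rankdata(s, method="average")
    rank_m = stats.rankdata(m, method="average")
    diff = np.abs(rank_s - rank_m)
    discordant = tuple(c for c, d in zip(contexts, diff) if d > window)
    return ValidationResult(
        n_contexts=n,
        rank_correlation=rho,
        n_concordant=n - len(discordant),
        discordant_contexts=discordant,
        window=window,
    )
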