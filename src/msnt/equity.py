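"""Wealth-quintile inequality statistics for service-coverage indicators.

Coverage of key interventions (institutional birth, caesarean section, ...)
is compared across five household-wealth quintiles.  Two statistics are
computed per country-indicator: the absolute gap between the richest and
poorest quintiles, and the inequality patterns index (IPI), which contrasts
the richest quintile's excess over the national mean with the poorest
quintile's shortfall:

    IPI = (q5 - mean) - (mean - q1) = q5 + q1 - 2 * mean        [pp]

A clearly positive IPI marks *top* inequality (the richest quintile stands
above all others); a clearly negative IPI marks *bottom* inequality (the
poorest stands below all others); values within a tolerance band (default
5 percentage points) are classified *linear*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import DomainError
from .profiles import PhaseProfile, phase_summaries

logger = logging.getLogger("msnt")

DEFAULT_IPI_TOLERANCE = 5.0  # percentage points

PATTERNS = ("top", "bottom", "linear")


@dataclass(frozen=True)
class QuintileCoverage:
    """Coverage by wealth quintile (q1 poorest ... q5 richest) plus national mean.

    When the national mean is absent it is computed as the unweighted mean of
    the five quintiles (with a warning — true national means are
    livebirth-weighted); per-quintile livebirth weights are honoured when
    provided.
    """

    country_id: str
    year: int
    indicator: str
    q1: float
    q2: float
    q3: float
    q4: float
    q5: float
    national_mean: float | None = None
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        qs = self.quintiles
        for i, v in enumerate(qs, start=1):
            if not 0 <= v <= 100:
                raise DomainError(
                    f"{self.country_id} {self.indicator}: q{i}={v} outside [0, 100]")
        if self.weights is not None:
            if len(self.weights) != 5 or any(w < 0 for w in self.weights) \
                    or sum(self.weights) == 0:
                raise DomainError("weights must be five nonnegative values, not all zero")
        if self.national_mean is None:
            if self.weights is not None:
                mean = float(np.average(qs, weights=self.weights))
            else:
                logger.warning("%s %s %s: national mean absent; using unweighted "
                               "quintile mean", self.country_id, self.year,
                               self.indicator)
                mean = float(np.mean(qs))
            object.__setattr__(self, "national_mean", mean)
        if not min(qs) - 1e-9 <= self.national_mean <= max(qs) + 1e-9:
            raise DomainError(
                f"{self.country_id} {self.indicator}: national mean "
                f"{self.national_mean} outside quintile range [{min(qs)}, {max(qs)}]")

    @property
    def quintiles(self) -> tuple[float, ...]:
        return (self.q1, self.q2, self.q3, self.q4, self.q5)


@dataclass(frozen=True)
class InequalityResult:
    """Gap and inequality patterns index for one quintile-coverage row."""

    gap: float
    ipi: float
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise DomainError(f"pattern must be one of {PATTERNS}, got {self.pattern}")


def quintile_gap(cov: QuintileCoverage) -> float:
    """Absolute richest-minus-poorest coverage gap in percentage points.

    Negative when the poorest quintile exceeds the richest.
    """
    return cov.q5 - cov.q1


def inequality_pattern_index(cov: QuintileCoverage,
                             tolerance: float = DEFAULT_IPI_TOLERANCE) -> InequalityResult:
    """Signed inequality patterns index and its top/bottom/linear label."""
    if tolerance < 0:
        raise DomainError(f"tolerance must be >= 0, got {tolerance}")
    ipi = cov.q5 + cov.q1 - 2.0 * cov.national_mean
    if ipi > tolerance:
        pattern = "top"
    elif ipi < -tolerance:
        pattern = "bottom"
    else:
        pattern = "linear"
    return InequalityResult(gap=quintile_gap(cov), ipi=ipi, pattern=pattern)


def equity_table(rows: Iterable[QuintileCoverage],
                 tolerance: float = DEFAULT_IPI_TOLERANCE) -> pd.DataFrame:
    """Gap/IPI/pattern for a collection of quintile-coverage rows."""
    recs = []
    for cov in rows:
        res = inequality_pattern_index(cov, tolerance)
        recs.append((cov.country_id, cov.year, cov.indicator, res.gap, res.ipi,
                     res.pattern))
    if not recs:
        raise DomainError("no quintile-coverage rows supplied")
    return pd.DataFrame(recs, columns=["country_id", "year", "indicator",
                                       "gap", "ipi", "pattern"])


def csec_quintile_summary(rows: Sequence[QuintileCoverage],
                          phases: pd.DataFrame,
                          indicator: str = "csec") -> dict[str, dict[int, PhaseProfile]]:
    """Phase-conditional medians of caesarean rates in the poorest and richest
    quintiles.

    ``rows`` are quintile-coverage records for caesarean section per 100
    livebirths; ``phases`` is an assignment table with ``country_id`` and
    ``phase`` columns.  Returns profiles keyed ``"poorest"`` and
    ``"richest"``, each phase -> :class:`PhaseProfile`.
    """
    sel = [r for r in rows if r.indicator == indicator]
    if not sel:
        raise DomainError(f"no quintile rows with indicator {indicator!r}")
    by_year = "year" in phases.columns
    if by_year:
        phase_map = {(c, int(y)): p for c, y, p in
                     zip(phases["country_id"].astype(str), phases["year"],
                         phases["phase"])}
    else:
        phase_map = dict(zip(phases["country_id"].astype(str), phases["phase"]))
    long_rows = []
    n_unmatched = 0
    for cov in sel:
        key = (str(cov.country_id), int(cov.year)) if by_year else str(cov.country_id)
        phase = phase_map.get(key)
        if phase is None:
            n_unmatched += 1
            continue
        long_rows.append((cov.country_id, int(phase), "poorest", cov.q1))
        long_rows.append((cov.country_id, int(phase), "richest", cov.q5))
    if n_unmatched:
        logger.warning("csec_quintile_summary: %d country(ies) without a phase "
                       "assignment excluded", n_unmatched)
    if not long_rows:
        raise DomainError("no caesarean rows matched a phase assignment")
    panel = pd.DataFrame(long_rows,
                         columns=["country_id", "phase", "indicator", "value"])
    return {
        "poorest": phase_summaries(panel, "poorest"),
        "richest": phase_summaries(panel, "richest"),
    }
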