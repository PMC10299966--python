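"""Five-phase mortality-transition classification.

A country-year is placed in one of five phases by comparing its maternal
mortality ratio and its combined stillbirth + neonatal mortality (SBN)
against two four-knot threshold vectors.  Phase 1 is the highest-mortality
phase (MMR >= 700 per 100 000 livebirths and SBN >= 80 per 1000 births);
phase 5 the lowest (MMR < 20 and SBN < 15).  A country reaches the next
phase only when *both* indicators have passed the knot, i.e. the combined
phase is the minimum of the two per-indicator phases.

Boundary convention: a value exactly at a knot has not yet passed it and
stays in the higher-mortality phase (phase 1 is printed as ">= 700", phase 5
as "< 20"; intermediate knots follow the same half-open rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (CombineMode, CountryYearEstimate, DomainError, Variant,
                   combine_sbn, sbn_to_mmr_ratio)

logger = logging.getLogger("msnt")

#: Maternal-mortality knots, deaths per 100 000 livebirths (phase 1|2, 2|3, 3|4, 4|5).
DEFAULT_MMR_KNOTS: tuple[float, ...] = (700.0, 300.0, 100.0, 20.0)
#: Stillbirth + neonatal knots, deaths per 1000 total births.
DEFAULT_SBN_KNOTS: tuple[float, ...] = (80.0, 55.0, 30.0, 15.0)
#: Neonatal-mortality-only alternative knots (per 1000 livebirths), for
#: analyses based on empirical neonatal data without stillbirths.
NMR_ONLY_KNOTS: tuple[float, ...] = (45.0, 30.0, 15.0, 5.0)

N_PHASES = 5


def _validate_knots(name: str, knots: Sequence[float]) -> tuple[float, ...]:
    knots = tuple(float(k) for k in knots)
    if len(knots) != 4:
        raise DomainError(f"{name} must have exactly 4 knots, got {len(knots)}")
    if any(not math.isfinite(k) or k <= 0 for k in knots):
        raise DomainError(f"{name} knots must be finite and > 0, got {knots}")
    if any(a <= b for a, b in zip(knots, knots[1:])):
        raise DomainError(f"{name} knots must be strictly decreasing, got {knots}")
    return knots


@dataclass(frozen=True)
class PhaseThresholds:
    """The four-knot threshold vectors defining the five phases."""

    mmr_knots: tuple[float, ...] = DEFAULT_MMR_KNOTS
    sbn_knots: tuple[float, ...] = DEFAULT_SBN_KNOTS

    def __post_init__(self) -> None:
        object.__setattr__(self, "mmr_knots", _validate_knots("mmr_knots", self.mmr_knots))
        object.__setattr__(self, "sbn_knots", _validate_knots("sbn_knots", self.sbn_knots))


@dataclass(frozen=True)
class PhaseAssignment:
    """Per-indicator phases plus the combined (min-rule) phase for one estimate."""

    country_id: str
    year: int
    phase_mmr: int
    phase_sbn: int
    phase: int = field(init=False)
    variant: Variant = "point"

    def __post_init__(self) -> None:
        for name, p in (("phase_mmr", self.phase_mmr), ("phase_sbn", self.phase_sbn)):
            if not 1 <= p <= N_PHASES:
                raise DomainError(f"{name} must be in 1..{N_PHASES}, got {p}")
        object.__setattr__(self, "phase", min(self.phase_mmr, self.phase_sbn))


def classify_indicator(value, knots: Sequence[float]):
    """Phase of one indicator value against one knot vector.

    A value at or above knot k has not passed it, so the phase is
    ``5 - (number of knots the value is strictly below ... )`` — concretely,
    ``5 minus the count of knots <= value``.  Accepts scalars or arrays.
    """
    knots = _validate_knots("knots", knots)
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise DomainError(f"indicator value must be finite and >= 0, got {value}")
    phase = N_PHASES - (arr[..., None] >= np.asarray(knots)).sum(axis=-1)
    if np.isscalar(value) or arr.ndim == 0:
        return int(phase)
    return phase.astype(int)


def classify_country(est: CountryYearEstimate,
                     thresholds: PhaseThresholds | None = None,
                     variant: Variant = "point",
                     mode: CombineMode = "approximate") -> PhaseAssignment:
    """Classify one country-year estimate into its transition phase.

    The SBN rate is built from the chosen variant's SBR and NMR via
    :func:`msnt.core.combine_sbn`; each indicator is classified separately
    and the combined phase is their minimum (both indicators must pass a
    knot before the country advances).
    """
    thresholds = thresholds or PhaseThresholds()
    mmr = est.value("mmr", variant)
    sbn = combine_sbn(est.value("sbr", variant), est.value("nmr", variant), mode=mode)
    return PhaseAssignment(
        country_id=est.country_id,
        year=int(est.year),
        phase_mmr=classify_indicator(mmr, thresholds.mmr_knots),
        phase_sbn=classify_indicator(sbn, thresholds.sbn_knots),
        variant=variant,
    )


def classify_panel(estimates: Iterable[CountryYearEstimate],
                   thresholds: PhaseThresholds | None = None,
                   variant: Variant = "point",
                   mode: CombineMode = "approximate") -> pd.DataFrame:
    """Classify a panel of estimates into a tidy assignment table.

    Returns a DataFrame with columns ``country_id, year, phase_mmr,
    phase_sbn, phase, variant``, one row per input estimate.
    """
    rows = [classify_country(e, thresholds, variant, mode) for e in estimates]
    if not rows:
        raise DomainError("cannot classify an empty panel")
    return pd.DataFrame(
        {
            "country_id": [a.country_id for a in rows],
            "year": [a.year for a in rows],
            "phase_mmr": [a.phase_mmr for a in rows],
            "phase_sbn": [a.phase_sbn for a in rows],
            "phase": [a.phase for a in rows],
            "variant": [a.variant for a in rows],
        }
    )


class KnotRatios(NamedTuple):
    """SBN:MMR ratios at the four transition knots, unrounded and rounded."""

    unrounded: tuple[float, ...]
    rounded: tuple[int, ...]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def knot_ratios(thresholds: PhaseThresholds | None = None) -> KnotRatios:
    """Ratio of SBN to maternal mortality at each transition knot.

    On the default thresholds the ratios climb from about 11 at the
    phase-1|2 knot to 18, 30 and 75 at the later knots — e.g. the
    phase-3|4 knot pairs SBN 55 per 1000 births with MMR 300 per
    100 000 livebirths, a ratio of 18.  The rounded variant rounds to the
    nearest integer, halves away from zero.
    """
    thresholds = thresholds or PhaseThresholds()
    unrounded = tuple(
        sbn_to_mmr_ratio(s, m)
        for s, m in zip(thresholds.sbn_knots, thresholds.mmr_knots)
    )
    return KnotRatios(unrounded, tuple(_round_half_away(r) for r in unrounded))


class PhaseSpanResult(NamedTuple):
    """Per-country lower-vs-upper-bound phase differences and their mean."""

    per_country: pd.DataFrame
    mean: float
    n_excluded: int


def uncertainty_phase_span(panel: Iterable[CountryYearEstimate],
                           thresholds: PhaseThresholds | None = None,
                           year: int | None = None,
                           mode: CombineMode = "approximate") -> PhaseSpanResult:
    """Sensitivity of the classification to the estimates' uncertainty bounds.

    For each country(-year) with both bounds available, classifies the lower
    and the upper bound and reports ``phase(lower) - phase(upper)``; lower
    bounds mean lower mortality and hence an equal-or-later phase, so the
    difference is always >= 0.  Countries missing any bound are excluded and
    counted.  The mean is reported unrounded; display at one decimal.
    """
    thresholds = thresholds or PhaseThresholds()
    rows = []
    n_excluded = 0
    for est in panel:
        if year is not None and int(est.year) != int(year):
            continue
        if not est.has_bounds:
            n_excluded += 1
            continue
        lo = classify_country(est, thresholds, "lower", mode)
        hi = classify_country(est, thresholds, "upper", mode)
        rows.append((est.country_id, int(est.year), lo.phase, hi.phase,
                     lo.phase - hi.phase))
    if n_excluded:
        logger.warning("uncertainty_phase_span: excluded %d estimate(s) with "
                       "missing bounds", n_excluded)
    if not rows:
        raise DomainError(
            f"no estimates with complete bounds{f' for year {year}' if year else ''}")
    per_country = pd.DataFrame(
        rows, columns=["country_id", "year", "phase_lower", "phase_upper", "span"])
    return PhaseSpanResult(per_country, float(per_country["span"].mean()), n_excluded)
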