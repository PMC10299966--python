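"""Phase-conditional covariate profiles, benchmarking, causes of death, policy scores.

Countries in the same transition phase share characteristic ranges of
fertility, coverage, workforce and financing indicators.  This module builds
those reference distributions (country median and IQR per phase), benchmarks
an individual country's value against them, aggregates cause-of-death tables
into three broad groups (infectious; health and nutritional status of woman
or baby; peripartum complications), and scores national abortion policies by
counting permitted legal grounds.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DomainError
from .phases import N_PHASES

logger = logging.getLogger("msnt")

QUARTILE_METHOD = "linear"  # numpy interpolation convention for median/Q1/Q3

CAUSE_GROUPS = ("group1_infectious", "group2_health_nutrition",
                "group3_peripartum", "other")

#: Short aliases accepted in mapping files.
_GROUP_ALIASES = {
    "1": "group1_infectious", "group1": "group1_infectious",
    "infectious": "group1_infectious",
    "2": "group2_health_nutrition", "group2": "group2_health_nutrition",
    "health_nutrition": "group2_health_nutrition",
    "3": "group3_peripartum", "group3": "group3_peripartum",
    "peripartum": "group3_peripartum",
    "other": "other",
}

DEFAULT_ABORTION_GROUNDS = (
    "save_womans_life",
    "physical_health",
    "mental_health",
    "rape_incest_or_fetal_impairment",
    "on_request",
)


@dataclass(frozen=True)
class PhaseProfile:
    """Phase-conditional summary of one covariate: n, median, Q1, Q3."""

    phase: int
    indicator: str
    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not 1 <= self.phase <= N_PHASES:
            raise DomainError(f"phase must be in 1..{N_PHASES}, got {self.phase}")
        if self.n < 1:
            raise DomainError("a profile needs at least one contributing country")
        if not self.q1 <= self.median <= self.q3:
            raise DomainError(
                f"quartiles must be ordered: q1={self.q1}, median={self.median}, "
                f"q3={self.q3}")


@dataclass(frozen=True)
class CauseGroupShares:
    """Percent of deaths in each of the three broad cause groups (plus other)."""

    group1_infectious: float
    group2_health_nutrition: float
    group3_peripartum: float
    other: float

    def __post_init__(self) -> None:
        vals = [getattr(self, g) for g in CAUSE_GROUPS]
        if any(v < 0 or v > 100 for v in vals):
            raise DomainError(f"shares must lie in [0, 100], got {vals}")
        if abs(sum(vals) - 100.0) > 1e-6:
            raise DomainError(f"shares must sum to 100, got {sum(vals)}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.group1_infectious, self.group2_health_nutrition,
                self.group3_peripartum, self.other)


@dataclass(frozen=True)
class AbortionPolicy:
    """Permission status of five legal grounds for abortion.

    The default grounds run from the most basic (saving the woman's life) to
    the most permissive (available on request); both the names and — in
    :func:`abortion_score` — the weights are configurable.
    """

    permitted: Mapping[str, bool]
    grounds: tuple[str, ...] = DEFAULT_ABORTION_GROUNDS

    def __post_init__(self) -> None:
        if len(self.grounds) != 5:
            raise DomainError(f"exactly five legal grounds required, got {len(self.grounds)}")
        missing = [g for g in self.grounds if g not in self.permitted]
        if missing:
            raise DomainError(f"policy missing grounds: {missing}")


def phase_summaries(panel: pd.DataFrame, indicator: str,
                    quartile_method: str = QUARTILE_METHOD) -> dict[int, PhaseProfile]:
    """Country median and quartiles of one covariate, per transition phase.

    Parameters
    ----------
    panel : DataFrame of covariate values joined to phase assignments, long
        format with columns ``country_id, phase, indicator, value`` (extra
        columns ignored).
    indicator : which covariate to profile; unknown names raise an error
        listing what is available.
    quartile_method : quantile interpolation convention passed to
        ``numpy.quantile`` (default ``"linear"``).

    Returns
    -------
    dict mapping phase -> :class:`PhaseProfile`; phases with no contributing
    country are absent from the result, not reported as zero.
    """
    for col in ("phase", "indicator", "value"):
        if col not in panel.columns:
            raise DomainError(f"panel is missing required column {col!r}")
    available = sorted(panel["indicator"].unique())
    sub = panel[panel["indicator"] == indicator]
    if sub.empty:
        raise DomainError(
            f"unknown indicator {indicator!r}; available: {available}")
    n_missing = int(sub["value"].isna().sum())
    if n_missing:
        logger.warning("phase_summaries(%s): dropped %d missing value(s)",
                       indicator, n_missing)
        sub = sub.dropna(subset=["value"])
    out: dict[int, PhaseProfile] = {}
    for phase, grp in sub.groupby("phase"):
        vals = grp["value"].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method=quartile_method)
        out[int(phase)] = PhaseProfile(int(phase), indicator, len(vals),
                                       float(med), float(q1), float(q3))
    return out


def benchmark_country(value: float, profile: PhaseProfile,
                      tolerance: float = 0.0) -> str:
    """Flag a country's value against a phase profile's IQR.

    Returns ``"typical"`` when the value lies within [Q1, Q3] (the band is
    widened multiplicatively by ``tolerance``), ``"above_iqr"`` or
    ``"below_iqr"`` otherwise.
    """
    if tolerance < 0:
        raise DomainError(f"tolerance must be >= 0, got {tolerance}")
    lo = profile.q1 * (1.0 - tolerance)
    hi = profile.q3 * (1.0 + tolerance)
    if value < lo:
        return "below_iqr"
    if value > hi:
        return "above_iqr"
    return "typical"


def load_default_cause_mapping(which: str) -> dict[str, str]:
    """Load the bundled cause -> group mapping for maternal, stillbirth or
    neonatal deaths.  The files are editable two-column CSV (cause, group)."""
    if which not in ("maternal", "stillbirth", "neonatal"):
        raise DomainError("which must be 'maternal', 'stillbirth' or 'neonatal'")
    text = (resources.files("msnt.data") / f"{which}_cause_groups.csv").read_text()
    reader = csv.DictReader(text.splitlines())
    return {row["cause"].strip(): row["group"].strip() for row in reader}


def cod_group_shares(cause_table: Mapping[str, float],
                     mapping: Mapping[str, str],
                     strict: bool = True) -> CauseGroupShares:
    """Aggregate a cause-of-death table into the three broad groups.

    ``cause_table`` maps cause names to death counts or percentages; the
    result is renormalised to sum to 100, so either works.  In strict mode
    every cause must have a mapping entry; in lenient mode unmapped causes
    are routed to "other" with a logged count.
    """
    if not cause_table:
        raise DomainError("cause table is empty")
    totals = dict.fromkeys(CAUSE_GROUPS, 0.0)
    n_unmapped = 0
    for cause, deaths in cause_table.items():
        if deaths < 0:
            raise DomainError(f"negative deaths for cause {cause!r}")
        raw = mapping.get(cause)
        if raw is None:
            if strict:
                raise DomainError(f"cause {cause!r} has no group mapping")
            n_unmapped += 1
            group = "other"
        else:
            group = _GROUP_ALIASES.get(str(raw).strip().lower())
            if group is None:
                raise DomainError(
                    f"cause {cause!r} maps to unknown group {raw!r}; "
                    f"expected one of {CAUSE_GROUPS}")
        totals[group] += float(deaths)
    if n_unmapped:
        logger.warning("cod_group_shares: %d unmapped cause(s) routed to 'other'",
                       n_unmapped)
    total = sum(totals.values())
    if total <= 0:
        raise DomainError("cause table sums to zero; shares undefined")
    # clamp float round-off so single-group tables stay within [0, 100]
    return CauseGroupShares(**{g: min(100.0 * v / total, 100.0)
                               for g, v in totals.items()})


def abortion_score(policy: AbortionPolicy,
                   weights: Sequence[float] | None = None) -> float:
    """Abortion-policy score on a 0–100 scale.

    0 means abortion is not legally permitted on any ground; 100 that all
    five grounds, including on request, are permitted.  Equal weights by
    default; a custom five-element weight vector is renormalised.
    """
    if weights is None:
        weights = [1.0] * 5
    weights = [float(w) for w in weights]
    if len(weights) != 5 or any(w < 0 for w in weights) or sum(weights) == 0:
        raise DomainError("weights must be five nonnegative values, not all zero")
    scale = 100.0 / sum(weights)
    return scale * sum(w for g, w in zip(policy.grounds, weights)
                       if policy.permitted[g])


def benchmark_table(values: Mapping[str, float],
                    profiles: Mapping[str, Mapping[int, PhaseProfile]] | Mapping[str, PhaseProfile],
                    phase: int, tolerance: float = 0.0) -> pd.DataFrame:
    """Benchmark several indicators of one country against one phase's profiles.

    ``profiles`` maps indicator -> (phase -> profile) as returned by
    :func:`phase_summaries`, or directly indicator -> profile.
    """
    rows = []
    for indicator, value in values.items():
        prof = profiles.get(indicator)
        if prof is None:
            raise DomainError(f"no profile for indicator {indicator!r}")
        if isinstance(prof, Mapping):
            if phase not in prof:
                raise DomainError(f"indicator {indicator!r} has no phase-{phase} profile")
            prof = prof[phase]
        rows.append((indicator, value, prof.median, prof.q1, prof.q3,
                     benchmark_country(value, prof, tolerance)))
    return pd.DataFrame(rows, columns=["indicator", "value", "phase_median",
                                       "phase_q1", "phase_q3", "flag"])
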