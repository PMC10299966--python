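"""Movement between transition phases across two time points.

Given phase assignments at a baseline year (t0) and a follow-up year (t1),
this module tabulates the 5x5 transition matrix and summarises progression
(advanced at least one phase, advanced exactly two) and regression among the
eligible countries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import DomainError
from .phases import N_PHASES

logger = logging.getLogger("msnt")

#: Countries below phase 5 at t0 — i.e. in phases 1 to 4 — can still progress;
#: both spellings name the same rule.  "all_phases_at_t0" includes phase-5
#: countries in the denominator.
ELIGIBILITY_RULES = ("below_phase5_at_t0", "phases_1_to_4_at_t0", "all_phases_at_t0")


@dataclass(frozen=True)
class TransitionRecord:
    """One country's phase at two time points."""

    country_id: str
    phase_t0: int
    phase_t1: int

    def __post_init__(self) -> None:
        for name, p in (("phase_t0", self.phase_t0), ("phase_t1", self.phase_t1)):
            if not 1 <= p <= N_PHASES:
                raise DomainError(f"{name} must be in 1..{N_PHASES}, got {p}")

    @property
    def delta(self) -> int:
        """Phase change, positive for progression; in [-4, 4]."""
        return self.phase_t1 - self.phase_t0


@dataclass(frozen=True)
class ProgressionSummary:
    """Counts and proportions of phase movement among eligible countries."""

    n_eligible: int
    n_progressed_ge1: int
    n_progressed_eq2: int
    n_progressed_ge2: int
    n_regressed: int

    def __post_init__(self) -> None:
        if self.n_eligible <= 0:
            raise DomainError("progression summary needs at least one eligible country")
        if not (0 <= self.n_progressed_eq2 <= self.n_progressed_ge2
                <= self.n_progressed_ge1 <= self.n_eligible):
            raise DomainError("inconsistent progression counts")

    @property
    def prop_progressed_ge1(self) -> float:
        return self.n_progressed_ge1 / self.n_eligible

    @property
    def prop_progressed_eq2(self) -> float:
        return self.n_progressed_eq2 / self.n_eligible

    @property
    def prop_regressed(self) -> float:
        return self.n_regressed / self.n_eligible

    def as_dict(self) -> dict:
        d = {f: getattr(self, f) for f in
             ("n_eligible", "n_progressed_ge1", "n_progressed_eq2",
              "n_progressed_ge2", "n_regressed")}
        d["pct_progressed_ge1"] = round(100 * self.prop_progressed_ge1)
        d["pct_progressed_eq2"] = round(100 * self.prop_progressed_eq2)
        d["pct_regressed"] = round(100 * self.prop_regressed)
        return d


def _as_phase_map(assignments) -> dict[str, int]:
    """Normalise a phase table (DataFrame with country_id/phase, mapping, or
    PhaseAssignment iterable) to a country -> phase dict, rejecting duplicates."""
    if isinstance(assignments, pd.DataFrame):
        pairs = list(zip(assignments["country_id"], assignments["phase"]))
    elif isinstance(assignments, Mapping):
        pairs = list(assignments.items())
    else:
        pairs = [(a.country_id, a.phase) for a in assignments]
    out: dict[str, int] = {}
    for cid, phase in pairs:
        if cid in out:
            raise DomainError(f"duplicate country {cid!r} in assignment set")
        phase = int(phase)
        if not 1 <= phase <= N_PHASES:
            raise DomainError(f"{cid}: phase must be in 1..{N_PHASES}, got {phase}")
        out[str(cid)] = phase
    return out


def match_assignments(assignments_t0, assignments_t1) -> list[TransitionRecord]:
    """Pair two assignment sets by country; unmatched countries are logged."""
    t0 = _as_phase_map(assignments_t0)
    t1 = _as_phase_map(assignments_t1)
    common = [c for c in t0 if c in t1]
    unmatched = (set(t0) | set(t1)) - set(common)
    if unmatched:
        logger.warning("transition matching: %d country(ies) present at only one "
                       "time point excluded: %s", len(unmatched),
                       ", ".join(sorted(unmatched)[:10]))
    return [TransitionRecord(c, t0[c], t1[c]) for c in common]


def transition_matrix(assignments_t0, assignments_t1) -> pd.DataFrame:
    """5x5 count matrix of phase at t0 (rows) against phase at t1 (columns).

    The matrix total equals the number of countries classified at both time
    points; countries present in only one set are excluded and logged.
    """
    records = match_assignments(assignments_t0, assignments_t1)
    phases = list(range(1, N_PHASES + 1))
    mat = pd.DataFrame(0, index=pd.Index(phases, name="phase_t0"),
                       columns=pd.Index(phases, name="phase_t1"))
    for rec in records:
        mat.loc[rec.phase_t0, rec.phase_t1] += 1
    return mat


def progression_summary(records: Sequence[TransitionRecord] | Iterable[TransitionRecord],
                        eligibility: str = "below_phase5_at_t0") -> ProgressionSummary:
    """Summarise progression and regression among eligible countries.

    ``eligibility`` selects the denominator: countries below phase 5 at t0
    (the default — phase-5 countries cannot progress further) or all
    classified countries (``"all_phases_at_t0"``).
    """
    if eligibility not in ELIGIBILITY_RULES:
        raise DomainError(
            f"unknown eligibility {eligibility!r}; expected one of {ELIGIBILITY_RULES}")
    records = list(records)
    if eligibility == "all_phases_at_t0":
        eligible = records
    else:
        eligible = [r for r in records if r.phase_t0 < N_PHASES]
    if not eligible:
        raise DomainError("no eligible countries for progression summary")
    deltas = [r.delta for r in eligible]
    return ProgressionSummary(
        n_eligible=len(eligible),
        n_progressed_ge1=sum(d >= 1 for d in deltas),
        n_progressed_eq2=sum(d == 2 for d in deltas),
        n_progressed_ge2=sum(d >= 2 for d in deltas),
        n_regressed=sum(d < 0 for d in deltas),
    )
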