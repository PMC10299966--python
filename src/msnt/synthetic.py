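"""Synthetic country-panel generator with the structure the transition model assumes.

The generator emulates the statistical shape of the UN mortality estimates
and the survey-derived covariate and wealth-quintile tables: correlated,
declining mortality indicators with stillbirth:neonatal ratios around
0.7–1.1; SBN-to-maternal-death ratios that rise as mortality falls (a
consequence of the phase-box geometry); phase-graded covariates; and
quintile coverage that shifts from top inequality in early phases to
near-linear patterns late in the transition.

Countries are assigned an intended phase and their mortality pair (MMR, SBN)
is drawn uniformly inside that phase's threshold box shrunk by an interior
margin, so classification can recover the intended phase exactly.  A truth
table records the intended phase of every country-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountryYearEstimate, DomainError
from .equity import QuintileCoverage
from .phases import DEFAULT_MMR_KNOTS, DEFAULT_SBN_KNOTS, N_PHASES

# Outer limits of the open-ended phase-1 and phase-5 boxes.  The caps are
# generous relative to the highest observed national estimates; the floors
# keep all rates strictly positive.
MMR_CAP, MMR_FLOOR = 1400.0, 3.0
SBN_CAP, SBN_FLOOR = 130.0, 3.0

REGIMES = ("top", "bottom", "linear")


@dataclass(frozen=True)
class CovariateSpec:
    """Per-phase median and IQR of one covariate, plus clip bounds."""

    medians: tuple[float, ...]
    iqr: tuple[tuple[float, float], ...]
    bounds: tuple[float | None, float | None] = (0.0, None)

    def __post_init__(self) -> None:
        if len(self.medians) != N_PHASES or len(self.iqr) != N_PHASES:
            raise DomainError("covariate spec needs one median and IQR per phase")
        for m, (q1, q3) in zip(self.medians, self.iqr):
            if not q1 <= m <= q3:
                raise DomainError(f"IQR ({q1}, {q3}) must bracket the median {m}")


def _reference_covariates() -> dict[str, CovariateSpec]:
    pct = (0.0, 100.0)
    return {
        "tfr": CovariateSpec(
            (6.1, 5.4, 2.8, 2.2, 1.5),
            ((5.8, 6.9), (4.0, 5.8), (2.0, 3.5), (1.6, 2.7), (1.4, 1.8)),
            (0.5, 9.0)),
        "adolescent_fertility": CovariateSpec(
            (105, 100, 60, 40, 15),
            ((85, 130), (80, 120), (48, 72), (32, 48), (12, 18)),
            (0.0, 250.0)),
        "anc1": CovariateSpec(
            (66, 80, 90, 95, 98),
            ((55, 75), (70, 88), (84, 95), (91, 98), (96, 99.5)), pct),
        "anc4": CovariateSpec(
            (44, 60, 75, 87, 94),
            ((35, 54), (50, 70), (66, 84), (80, 92), (90, 97)), pct),
        "institutional_birth": CovariateSpec(
            (36, 60, 80, 95, 99),
            ((28, 45), (50, 70), (72, 88), (90, 98), (97.5, 99.8)), pct),
        "csec": CovariateSpec(
            (2, 5, 10, 18, 25),
            ((1.5, 2.6), (4, 6.5), (8, 13), (15, 22), (20, 31)), pct),
        "abortion_score": CovariateSpec(
            (51, 55, 68, 75, 86),
            ((42, 62), (45, 66), (56, 80), (62, 88), (72, 97)), pct),
        "health_exp_pc": CovariateSpec(
            (30, 45, 85, 180, 320),
            ((24, 38), (36, 57), (68, 107), (145, 225), (260, 400)),
            (1.0, None)),
        "workforce_density": CovariateSpec(
            (4, 8, 20, 43, 80),
            ((3.2, 5), (6.5, 10), (16, 25), (35, 54), (65, 100)),
            (0.1, None)),
        "skills_mix_ratio": CovariateSpec(
            (6, 8, 4.5, 2, 2.2),
            ((4.8, 7.5), (6.5, 10), (3.6, 5.6), (1.6, 2.7), (1.8, 2.8)),
            (0.2, None)),
    }


# Institutional-birth quintile centres (q1..q5, poorest to richest) per phase.
# Early phases show top inequality with a ~50pp rich-poor gap; phase 3 bottom
# inequality; late phases near-linear with small gaps (7pp, then 2pp).
_INST_QUINTILES = (
    (15.0, 22.0, 29.0, 36.0, 65.0),
    (35.0, 43.0, 51.0, 59.0, 85.0),
    (45.0, 72.0, 79.0, 86.0, 92.0),
    (91.0, 92.75, 94.5, 96.25, 98.0),
    (97.0, 97.5, 98.0, 98.5, 99.0),
)

# Caesarean rates per 100 livebirths by quintile and phase: below 1-2% among
# the poorest in early phases, with the richest quintile rising from ~10%
# (phase 2) to ~28% (phase 3) ahead of the poorest (4% -> 15% at phase 3|4).
_CSEC_QUINTILES = (
    (0.5, 1.0, 1.7, 2.8, 5.0),
    (1.5, 2.8, 4.5, 7.0, 10.0),
    (4.0, 8.0, 13.0, 20.0, 28.0),
    (15.0, 19.0, 23.0, 27.0, 32.0),
    (22.0, 25.0, 28.0, 30.0, 33.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic panel.

    Defaults emulate the source estimates: two survey years twenty years
    apart, ~2%/year annual rates of reduction, relative uncertainty
    half-widths of 30/20/10% for MMR/SBR/NMR, stillbirth:neonatal ratios in
    (0.7, 1.1), covariate gradients matching the printed phase medians, and
    a 63% per-interval progression probability (3% regression) so roughly
    two thirds of non-terminal countries advance a phase.
    """

    n_per_phase: tuple[int, ...] = (60, 60, 60, 60, 60)
    years: tuple[int, ...] = (2000, 2020)
    arr_mmr: float = 2.0   # annual rate of reduction, %/year
    arr_sbn: float = 2.0
    trend_noise_sd: float = 0.05  # lognormal sd on the 20-year decline factor
    halfwidth_mmr: float = 0.30   # uncertainty half-width, fraction of point
    halfwidth_sbr: float = 0.20
    halfwidth_nmr: float = 0.10
    sb_nn_ratio_range: tuple[float, float] = (0.7, 1.1)
    box_margin: float = 0.10      # interior margin of each phase box
    progression_prob: tuple[float, ...] = (0.63, 0.63, 0.63, 0.63, 0.0)
    regression_prob: tuple[float, ...] = (0.0, 0.03, 0.03, 0.03, 0.03)
    covariates: Mapping[str, CovariateSpec] = field(default_factory=_reference_covariates)
    inequality_regimes: tuple[str, ...] = ("top", "top", "bottom", "linear", "linear")
    inst_birth_quintiles: tuple[tuple[float, ...], ...] = _INST_QUINTILES
    csec_quintiles: tuple[tuple[float, ...], ...] = _CSEC_QUINTILES
    quintile_noise_sd: float = 1.5       # additive pp noise on quintile coverage
    csec_quintile_rel_sd: float = 0.15   # relative noise on caesarean quintiles
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_phase) != N_PHASES or any(n < 0 for n in self.n_per_phase):
            raise DomainError("n_per_phase needs five nonnegative counts")
        if sum(self.n_per_phase) == 0:
            raise DomainError("at least one country must be generated")
        if len(self.years) < 1 or list(self.years) != sorted(set(self.years)):
            raise DomainError("years must be strictly increasing")
        for name in ("progression_prob", "regression_prob"):
            probs = getattr(self, name)
            if len(probs) != N_PHASES or any(not 0 <= p <= 1 for p in probs):
                raise DomainError(f"{name} needs five probabilities in [0, 1]")
        for p, r in zip(self.progression_prob, self.regression_prob):
            if p + r > 1:
                raise DomainError("progression + regression probability exceeds 1")
        lo, hi = self.sb_nn_ratio_range
        if not 0 < lo < hi < 5:
            raise DomainError("sb_nn_ratio_range must satisfy 0 < lo < hi < 5")
        if not 0 <= self.box_margin < 0.5:
            raise DomainError("box_margin must be in [0, 0.5)")
        for name in ("halfwidth_mmr", "halfwidth_sbr", "halfwidth_nmr"):
            if not 0 <= getattr(self, name) < 1:
                raise DomainError(f"{name} must be in [0, 1)")
        if len(self.inequality_regimes) != N_PHASES or \
                any(r not in REGIMES for r in self.inequality_regimes):
            raise DomainError(f"inequality_regimes must be five of {REGIMES}")


def reference_config(**overrides) -> GeneratorConfig:
    """The bundled reference study conditions.

    Covariate medians equal the printed phase medians (TFR 6.1/5.4/2.8/2.2/
    1.5 children per woman; institutional birth 36 -> 99%; ANC1 66 -> 98%;
    ANC4 44 -> 94%; caesarean 2 -> 25%), so end-to-end runs on synthetic
    data reproduce the qualitative phase gradients.
    """
    return GeneratorConfig(**overrides)


@dataclass(frozen=True)
class SyntheticPanel:
    """One generated panel: estimates, covariates, quintile coverage, truth."""

    estimates: tuple[CountryYearEstimate, ...]
    panel: pd.DataFrame
    covariates: pd.DataFrame
    quintiles: tuple[QuintileCoverage, ...]
    quintiles_table: pd.DataFrame
    truth: pd.DataFrame

    def to_dir(self, outdir: str | Path) -> dict[str, Path]:
        """Write panel.csv, covariates.csv, quintiles.csv and truth.csv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("panel", self.panel), ("covariates", self.covariates),
                         ("quintiles", self.quintiles_table), ("truth", self.truth)):
            paths[name] = outdir / f"{name}.csv"
            df.to_csv(paths[name], index=False)
        return paths


def _phase_boxes(knots: Sequence[float], cap: float, floor: float,
                 margin: float) -> list[tuple[float, float]]:
    """(lo, hi) sampling box per phase, shrunk by ``margin`` of the box width."""
    edges = [cap, *knots, floor]  # edges[p-1] .. edges[p] bound phase p
    boxes = []
    for p in range(1, N_PHASES + 1):
        hi, lo = edges[p - 1], edges[p]
        w = (hi - lo) * margin
        boxes.append((lo + w, hi - w))
    return boxes


def _split_sbn(sbn: float, ratio: float) -> tuple[float, float]:
    """Split an SBN rate (simple-sum convention) into (sbr, nmr) such that the
    exact stillbirth:neonatal ratio sbr / (nmr * (1 - sbr/1000)) equals ``ratio``.

    Solving r*(sbn - sbr)*(1 - sbr/1000) = sbr for sbr gives a quadratic;
    the smaller root is the admissible one (0 < sbr < sbn).
    """
    a = ratio / 1000.0
    b = -(ratio * (1.0 + sbn / 1000.0) + 1.0)
    c = ratio * sbn
    disc = b * b - 4.0 * a * c
    sbr = (-b - np.sqrt(disc)) / (2.0 * a)
    return float(sbr), float(sbn - sbr)


def _draw_quintiles(centres: Sequence[float], rng: np.random.Generator,
                    sd: float, rel: bool) -> tuple[float, ...]:
    centres = np.asarray(centres, dtype=float)
    noise_sd = centres * sd if rel else np.full(5, sd)
    vals = np.clip(rng.normal(centres, noise_sd), 0.0, 100.0)
    return tuple(float(v) for v in vals)


def generate_panel(config: GeneratorConfig | None = None,
                   seed: int | None = None) -> SyntheticPanel:
    """Generate a synthetic country panel under the given study conditions.

    A fixed seed yields bit-identical output.  One named random stream per
    output table (mortality, covariates, quintiles) is spawned from the
    seed, so adding a table never perturbs the existing ones.
    """
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(3)
    rng_mort = np.random.default_rng(streams[0])
    rng_cov = np.random.default_rng(streams[1])
    rng_quint = np.random.default_rng(streams[2])

    mmr_boxes = _phase_boxes(DEFAULT_MMR_KNOTS, MMR_CAP, MMR_FLOOR, config.box_margin)
    sbn_boxes = _phase_boxes(DEFAULT_SBN_KNOTS, SBN_CAP, SBN_FLOOR, config.box_margin)

    # Stable country ids: C0001.. in intended-phase order.
    country_phase0: list[tuple[str, int]] = []
    idx = 1
    for phase in range(1, N_PHASES + 1):
        for _ in range(config.n_per_phase[phase - 1]):
            country_phase0.append((f"C{idx:04d}", phase))
            idx += 1

    estimates: list[CountryYearEstimate] = []
    truth_rows: list[tuple[str, int, int]] = []
    phase_by_country_year: dict[tuple[str, int], int] = {}

    rlo, rhi = config.sb_nn_ratio_range
    for cid, phase in country_phase0:
        mmr = sbn = None
        for i, year in enumerate(config.years):
            if i == 0:
                mmr = rng_mort.uniform(*mmr_boxes[phase - 1])
                sbn = rng_mort.uniform(*sbn_boxes[phase - 1])
            else:
                span = config.years[i] - config.years[i - 1]
                u = rng_mort.uniform()
                if u < config.progression_prob[phase - 1] and phase < N_PHASES:
                    phase += 1
                    mmr = rng_mort.uniform(*mmr_boxes[phase - 1])
                    sbn = rng_mort.uniform(*sbn_boxes[phase - 1])
                elif u < (config.progression_prob[phase - 1]
                          + config.regression_prob[phase - 1]) and phase > 1:
                    phase -= 1
                    mmr = rng_mort.uniform(*mmr_boxes[phase - 1])
                    sbn = rng_mort.uniform(*sbn_boxes[phase - 1])
                else:
                    decline_m = (1.0 - config.arr_mmr / 100.0) ** span
                    decline_s = (1.0 - config.arr_sbn / 100.0) ** span
                    noise = rng_mort.lognormal(0.0, config.trend_noise_sd, size=2)
                    mmr = float(np.clip(mmr * decline_m * noise[0], *mmr_boxes[phase - 1]))
                    sbn = float(np.clip(sbn * decline_s * noise[1], *sbn_boxes[phase - 1]))
            ratio = rng_mort.uniform(rlo, rhi)
            sbr, nmr = _split_sbn(sbn, ratio)
            estimates.append(CountryYearEstimate(
                country_id=cid, year=int(year),
                mmr=mmr, sbr=sbr, nmr=nmr,
                mmr_lower=mmr * (1 - config.halfwidth_mmr),
                mmr_upper=mmr * (1 + config.halfwidth_mmr),
                sbr_lower=sbr * (1 - config.halfwidth_sbr),
                sbr_upper=sbr * (1 + config.halfwidth_sbr),
                nmr_lower=nmr * (1 - config.halfwidth_nmr),
                nmr_upper=nmr * (1 + config.halfwidth_nmr),
            ))
            truth_rows.append((cid, int(year), phase))
            phase_by_country_year[(cid, int(year))] = phase

    cov_rows = []
    for cid, _ in country_phase0:
        for year in config.years:
            phase = phase_by_country_year[(cid, int(year))]
            for name, spec in config.covariates.items():
                med = spec.medians[phase - 1]
                q1, q3 = spec.iqr[phase - 1]
                sigma = (q3 - q1) / 1.349  # normal IQR -> sd
                value = rng_cov.normal(med, sigma)
                lo, hi = spec.bounds
                value = float(np.clip(value, lo if lo is not None else -np.inf,
                                      hi if hi is not None else np.inf))
                cov_rows.append((cid, int(year), name, value))
    covariates = pd.DataFrame(cov_rows,
                              columns=["country_id", "year", "indicator", "value"])

    quintiles: list[QuintileCoverage] = []
    for cid, _ in country_phase0:
        for year in config.years:
            phase = phase_by_country_year[(cid, int(year))]
            inst = _draw_quintiles(config.inst_birth_quintiles[phase - 1],
                                   rng_quint, config.quintile_noise_sd, rel=False)
            quintiles.append(QuintileCoverage(
                cid, int(year), "institutional_birth", *inst,
                national_mean=float(np.mean(inst))))
            csec = _draw_quintiles(config.csec_quintiles[phase - 1],
                                   rng_quint, config.csec_quintile_rel_sd, rel=True)
            quintiles.append(QuintileCoverage(
                cid, int(year), "csec", *csec,
                national_mean=float(np.mean(csec))))

    panel = pd.DataFrame({
        "country_id": [e.country_id for e in estimates],
        "year": [e.year for e in estimates],
        "mmr": [e.mmr for e in estimates],
        "mmr_lower": [e.mmr_lower for e in estimates],
        "mmr_upper": [e.mmr_upper for e in estimates],
        "sbr": [e.sbr for e in estimates],
        "sbr_lower": [e.sbr_lower for e in estimates],
        "sbr_upper": [e.sbr_upper for e in estimates],
        "nmr": [e.nmr for e in estimates],
        "nmr_lower": [e.nmr_lower for e in estimates],
        "nmr_upper": [e.nmr_upper for e in estimates],
    })
    quintiles_table = pd.DataFrame({
        "country_id": [q.country_id for q in quintiles],
        "year": [q.year for q in quintiles],
        "indicator": [q.indicator for q in quintiles],
        "q1": [q.q1 for q in quintiles],
        "q2": [q.q2 for q in quintiles],
        "q3": [q.q3 for q in quintiles],
        "q4": [q.q4 for q in quintiles],
        "q5": [q.q5 for q in quintiles],
        "national_mean": [q.national_mean for q in quintiles],
    })
    truth = pd.DataFrame(truth_rows, columns=["country_id", "year", "phase"])
    return SyntheticPanel(tuple(estimates), panel, covariates,
                          tuple(quintiles), quintiles_table, truth)
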