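"""Readers, writers, run configuration and the report generator.

All inputs and outputs are small country-level tables in plain delimited
text (comma by default, tab accepted).  Readers validate every row against
the domain invariants and abort with a row-numbered error report rather than
propagating malformed data; rows with missing point estimates are dropped
and counted.  Analysis stages are deterministic; all randomness lives in
:mod:`msnt.synthetic`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .core import CountryYearEstimate, DomainError
from .equity import DEFAULT_IPI_TOLERANCE, QuintileCoverage, equity_table
from .phases import (PhaseThresholds, classify_panel, knot_ratios,
                     uncertainty_phase_span)
from .profiles import phase_summaries
from .transitions import match_assignments, progression_summary, transition_matrix

logger = logging.getLogger("msnt")

#: Canonical panel column names; a column map translates source headers.
PANEL_COLUMNS = ("country_id", "year", "mmr", "mmr_lower", "mmr_upper",
                 "sbr", "sbr_lower", "sbr_upper", "nmr", "nmr_lower",
                 "nmr_upper", "livebirths")
REQUIRED_PANEL_COLUMNS = ("country_id", "year", "mmr", "sbr", "nmr")


class PanelValidationError(DomainError):
    """Raised when panel rows violate invariants; carries all row errors."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "\n  ".join(self.errors[:20])
        more = f"\n  ... and {len(self.errors) - 20} more" if len(self.errors) > 20 else ""
        super().__init__(f"{len(self.errors)} invalid panel row(s):\n  {preview}{more}")


@dataclass(frozen=True)
class PanelReadResult:
    """Validated estimates plus row accounting for the stage log."""

    estimates: tuple[CountryYearEstimate, ...]
    n_read: int
    n_dropped: int
    n_bounds_defaulted: int


def read_panel(path: str | Path, column_map: Mapping[str, str] | None = None,
               delimiter: str | None = None) -> PanelReadResult:
    """Read and validate a country-year mortality panel.

    ``column_map`` maps canonical names to the file's headers (e.g.
    ``{"mmr": "MatMortRatio"}``).  Missing bound columns or cells default to
    the point estimate with a warning count; rows with missing point
    estimates are dropped and counted; any invariant violation aborts the
    read with a report naming each bad row and field.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter)
    column_map = dict(column_map or {})
    rename = {src: canon for canon, src in column_map.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(
            [f"missing required column(s): {', '.join(missing)}"])

    estimates: list[CountryYearEstimate] = []
    errors: list[str] = []
    seen: set[tuple[str, int]] = set()
    n_dropped = 0
    n_defaulted = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = row._asdict()
        if any(pd.isna(rec.get(c)) for c in REQUIRED_PANEL_COLUMNS):
            n_dropped += 1
            continue
        kwargs = {"country_id": str(rec["country_id"]), "year": int(rec["year"])}
        for ind in ("mmr", "sbr", "nmr"):
            kwargs[ind] = float(rec[ind])
            for side in ("lower", "upper"):
                col = f"{ind}_{side}"
                val = rec.get(col)
                if val is None or pd.isna(val):
                    kwargs[col] = kwargs[ind]
                    n_defaulted += 1
                else:
                    kwargs[col] = float(val)
        lb = rec.get("livebirths")
        if lb is not None and not pd.isna(lb):
            kwargs["livebirths"] = float(lb)
        try:
            est = CountryYearEstimate(**kwargs)
        except (DomainError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
            continue
        key = (est.country_id, est.year)
        if key in seen:
            errors.append(f"row {i}: duplicate country-year {key}")
            continue
        seen.add(key)
        estimates.append(est)
    if errors:
        raise PanelValidationError(errors)
    if n_defaulted:
        logger.warning("read_panel(%s): %d missing bound cell(s) defaulted to "
                       "the point estimate", path.name, n_defaulted)
    logger.info("read_panel(%s): rows_in=%d kept=%d dropped=%d bounds_defaulted=%d",
                path.name, len(df), len(estimates), n_dropped, n_defaulted)
    return PanelReadResult(tuple(estimates), len(df), n_dropped, n_defaulted)


def write_panel(estimates: Sequence[CountryYearEstimate], path: str | Path) -> Path:
    """Write estimates to delimited text; round-trips through read_panel."""
    path = Path(path)
    rows = []
    for e in estimates:
        rows.append({c: getattr(e, c) for c in PANEL_COLUMNS})
    pd.DataFrame(rows, columns=list(PANEL_COLUMNS)).to_csv(path, index=False)
    return path


def read_thresholds(path: str | Path) -> PhaseThresholds:
    """Load a thresholds YAML file: two 4-element lists, validated on load."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or not {"mmr_knots", "sbn_knots"} <= set(raw):
        raise DomainError(
            f"{path}: thresholds file must define 'mmr_knots' and 'sbn_knots'")
    return PhaseThresholds(tuple(raw["mmr_knots"]), tuple(raw["sbn_knots"]))


def read_covariates(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read a long-format covariate table (country_id, year, indicator, value)."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in ("country_id", "year", "indicator", "value")
               if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: covariate table missing column(s) {missing}")
    df["country_id"] = df["country_id"].astype(str)
    return df


def read_quintiles(path: str | Path, delimiter: str = ",") -> list[QuintileCoverage]:
    """Read quintile-coverage rows; national_mean optional (computed if absent)."""
    df = pd.read_csv(path, sep=delimiter)
    needed = ["country_id", "year", "indicator", "q1", "q2", "q3", "q4", "q5"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: quintile table missing column(s) {missing}")
    rows = []
    for rec in df.to_dict("records"):
        mean = rec.get("national_mean")
        rows.append(QuintileCoverage(
            str(rec["country_id"]), int(rec["year"]), str(rec["indicator"]),
            *(float(rec[f"q{i}"]) for i in range(1, 6)),
            national_mean=None if mean is None or pd.isna(mean) else float(mean)))
    return rows


@dataclass(frozen=True)
class RunConfig:
    """End-to-end report run: inputs, analysis options, output directory."""

    panel_path: Path
    outdir: Path
    years: tuple[int, int] = (2000, 2020)
    covariates_path: Path | None = None
    quintiles_path: Path | None = None
    thresholds_path: Path | None = None
    column_map: Mapping[str, str] = field(default_factory=dict)
    variant: str = "point"
    combine_mode: str = "approximate"
    quartile_method: str = "linear"
    ipi_tolerance: float = DEFAULT_IPI_TOLERANCE
    eligibility: str = "below_phase5_at_t0"

    def __post_init__(self) -> None:
        for name in ("panel_path", "covariates_path", "quintiles_path",
                     "thresholds_path"):
            p = getattr(self, name)
            if p is not None:
                object.__setattr__(self, name, Path(p))
                if not Path(p).exists():
                    raise DomainError(f"{name}: {p} does not exist")
        object.__setattr__(self, "outdir", Path(self.outdir))
        if len(self.years) != 2 or self.years[0] >= self.years[1]:
            raise DomainError("years must be an increasing (t0, t1) pair")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_report(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Produces phase counts per year, the transition matrix and progression
    summary, the knot ratios, phase profiles for every covariate, and equity
    summaries, as delimited text plus a machine-readable ``summary.json``
    carrying provenance (input hashes, thresholds, package version).
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = (read_thresholds(config.thresholds_path)
                  if config.thresholds_path else PhaseThresholds())
    stage = "read_panel"
    summary: dict = {
        "package_version": __version__,
        "thresholds": {"mmr_knots": thresholds.mmr_knots,
                       "sbn_knots": thresholds.sbn_knots},
        "inputs": {"panel": _sha256(config.panel_path)},
        "options": {"variant": config.variant, "combine_mode": config.combine_mode,
                    "quartile_method": config.quartile_method,
                    "ipi_tolerance": config.ipi_tolerance,
                    "eligibility": config.eligibility},
    }
    try:
        result = read_panel(config.panel_path, config.column_map)
        t0, t1 = config.years

        stage = "classify"
        by_year = {}
        for year in (t0, t1):
            ests = [e for e in result.estimates if e.year == year]
            if not ests:
                raise DomainError(f"no estimates for year {year}")
            by_year[year] = classify_panel(ests, thresholds, config.variant,
                                           config.combine_mode)
        phases_df = pd.concat(by_year.values(), ignore_index=True)
        phases_df.to_csv(outdir / "phases.csv", index=False)
        counts = (phases_df.groupby(["year", "phase"]).size()
                  .rename("n_countries").reset_index())
        counts.to_csv(outdir / "phase_counts.csv", index=False)
        summary["phase_counts"] = {
            int(y): {int(p): int(n) for p, n in
                     g.set_index("phase")["n_countries"].items()}
            for y, g in counts.groupby("year")}

        stage = "knot_ratios"
        kr = knot_ratios(thresholds)
        pd.DataFrame({"knot": [1, 2, 3, 4], "unrounded": kr.unrounded,
                      "rounded": kr.rounded}).to_csv(outdir / "knot_ratios.csv",
                                                     index=False)
        summary["knot_ratios"] = {"unrounded": kr.unrounded, "rounded": kr.rounded}

        stage = "uncertainty_span"
        if all(e.has_bounds for e in result.estimates):
            spans = {}
            for year in (t0, t1):
                res = uncertainty_phase_span(result.estimates, thresholds, year,
                                             config.combine_mode)
                spans[int(year)] = round(res.mean, 1)
            summary["mean_phase_span"] = spans

        stage = "transitions"
        matrix = transition_matrix(by_year[t0], by_year[t1])
        matrix.to_csv(outdir / "transition_matrix.csv")
        records = match_assignments(by_year[t0], by_year[t1])
        prog = progression_summary(records, config.eligibility)
        summary["transitions"] = prog.as_dict()

        stage = "profiles"
        if config.covariates_path is not None:
            cov = read_covariates(config.covariates_path)
            profile_rows = []
            for year in (t0, t1):
                joined = cov[cov["year"] == year].merge(
                    by_year[year][["country_id", "phase"]], on="country_id")
                for indicator in sorted(joined["indicator"].unique()):
                    for phase, prof in phase_summaries(
                            joined, indicator, config.quartile_method).items():
                        profile_rows.append((year, indicator, phase, prof.n,
                                             prof.median, prof.q1, prof.q3))
            pd.DataFrame(profile_rows,
                         columns=["year", "indicator", "phase", "n", "median",
                                  "q1", "q3"]).to_csv(outdir / "profiles.csv",
                                                      index=False)
            summary["inputs"]["covariates"] = _sha256(config.covariates_path)

        stage = "equity"
        if config.quintiles_path is not None:
            quint = read_quintiles(config.quintiles_path)
            eq = equity_table(quint, config.ipi_tolerance)
            eq.to_csv(outdir / "equity.csv", index=False)
            summary["equity_patterns"] = (
                eq.groupby(["year", "pattern"]).size().rename("n").reset_index()
                .pivot(index="year", columns="pattern", values="n")
                .fillna(0).astype(int).to_dict("index"))
            summary["inputs"]["quintiles"] = _sha256(config.quintiles_path)

        stage = "summary"
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                        default=str))
    except Exception as exc:
        raise DomainError(f"report stage '{stage}' failed: {exc}") from exc
    logger.info("run_report: wrote report bundle to %s", outdir)
    return summary
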