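"""Core mortality indicators and the rate constructions that make them comparable.

The three indicators live on different denominators:

* maternal mortality ratio (MMR) — maternal deaths per 100 000 livebirths;
* stillbirth rate (SBR) — late-gestation fetal deaths per 1000 total births
  (livebirths + stillbirths);
* neonatal mortality rate (NMR) — deaths in days 0–27 per 1000 livebirths.

This module defines the validated country-year estimate record and the three
derived quantities the transition model runs on: the combined stillbirth plus
neonatal rate (SBN, per 1000 total births), the SBN-to-maternal-death ratio,
and the stillbirth-to-neonatal-death ratio.

Scalar functions raise :class:`DomainError` on undefined input; the ``*_batch``
variants propagate NaN and log a count, so one degenerate row cannot abort a
multi-country run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

logger = logging.getLogger("msnt")

#: Calendar years accepted by :class:`CountryYearEstimate`.
VALID_YEAR_RANGE: tuple[int, int] = (1950, 2030)

CombineMode = Literal["exact", "approximate"]
Variant = Literal["point", "lower", "upper"]

VARIANTS: tuple[str, ...] = ("point", "lower", "upper")
INDICATORS: tuple[str, ...] = ("mmr", "sbr", "nmr")


class DomainError(ValueError):
    """An input lies outside the domain of a rate construction."""


def _check_interval(name: str, point: float, lower: float | None,
                    upper: float | None) -> None:
    if not math.isfinite(point) or point < 0:
        raise DomainError(f"{name} point estimate must be finite and >= 0, got {point}")
    if lower is not None:
        if not math.isfinite(lower) or lower < 0 or lower > point:
            raise DomainError(
                f"{name} lower bound must satisfy 0 <= lower <= point, "
                f"got lower={lower}, point={point}")
    if upper is not None:
        if not math.isfinite(upper) or upper < point:
            raise DomainError(
                f"{name} upper bound must satisfy upper >= point, "
                f"got upper={upper}, point={point}")


@dataclass(frozen=True)
class CountryYearEstimate:
    """One country-year's three mortality indicators with uncertainty bounds.

    Bounds may be ``None`` when the source table carries only point
    estimates; operations that need a bound raise a named error instead of
    silently substituting the point.
    """

    country_id: str
    year: int
    mmr: float
    sbr: float
    nmr: float
    mmr_lower: float | None = None
    mmr_upper: float | None = None
    sbr_lower: float | None = None
    sbr_upper: float | None = None
    nmr_lower: float | None = None
    nmr_upper: float | None = None
    livebirths: float | None = None

    def __post_init__(self) -> None:
        if not self.country_id:
            raise DomainError("country_id must be a non-empty string")
        lo, hi = VALID_YEAR_RANGE
        if not lo <= int(self.year) <= hi:
            raise DomainError(
                f"{self.country_id}: year {self.year} outside valid range {lo}-{hi}")
        _check_interval("mmr", self.mmr, self.mmr_lower, self.mmr_upper)
        _check_interval("sbr", self.sbr, self.sbr_lower, self.sbr_upper)
        _check_interval("nmr", self.nmr, self.nmr_lower, self.nmr_upper)
        for name, point, upper in (("sbr", self.sbr, self.sbr_upper),
                                   ("nmr", self.nmr, self.nmr_upper)):
            if max(point, upper if upper is not None else 0.0) >= 1000:
                raise DomainError(f"{name} must be < 1000 per 1000 births")
        if self.livebirths is not None and self.livebirths < 0:
            raise DomainError("livebirths must be >= 0")

    @property
    def has_bounds(self) -> bool:
        """True when all six lower/upper bounds are present."""
        return None not in (self.mmr_lower, self.mmr_upper, self.sbr_lower,
                            self.sbr_upper, self.nmr_lower, self.nmr_upper)

    def value(self, indicator: str, variant: Variant = "point") -> float:
        """Return one indicator under one estimate variant.

        Raises :class:`DomainError` if the requested bound is absent,
        naming the country-year.
        """
        if indicator not in INDICATORS:
            raise DomainError(f"unknown indicator {indicator!r}; expected one of {INDICATORS}")
        if variant == "point":
            return float(getattr(self, indicator))
        if variant not in VARIANTS:
            raise DomainError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        bound = getattr(self, f"{indicator}_{variant}")
        if bound is None:
            raise DomainError(
                f"{self.country_id} {self.year}: missing {indicator} {variant} bound")
        return float(bound)


@dataclass(frozen=True)
class CombinedRates:
    """Derived rates for one estimate: SBN plus the two diagnostic ratios.

    Undefined ratios (zero denominator) are ``None``, never silently 0.
    """

    sbn: float
    sbn_to_mmr_ratio: float | None
    sb_to_nn_ratio: float | None

    @classmethod
    def from_estimate(cls, est: CountryYearEstimate, variant: Variant = "point",
                      mode: CombineMode = "approximate") -> "CombinedRates":
        mmr = est.value("mmr", variant)
        sbr = est.value("sbr", variant)
        nmr = est.value("nmr", variant)
        sbn = combine_sbn(sbr, nmr, mode=mode)
        return cls(
            sbn=sbn,
            sbn_to_mmr_ratio=sbn_to_mmr_ratio(sbn, mmr) if mmr > 0 else None,
            sb_to_nn_ratio=sb_to_nn_ratio(sbr, nmr) if nmr > 0 else None,
        )


def combine_sbn(sbr: float, nmr: float, mode: CombineMode = "approximate") -> float:
    """Combine stillbirth and neonatal mortality onto the total-births denominator.

    Parameters
    ----------
    sbr : stillbirths per 1000 total births, ``0 <= sbr < 1000``.
    nmr : neonatal deaths per 1000 livebirths, ``>= 0``.
    mode : ``"approximate"`` returns the simple sum ``sbr + nmr`` (the knot
        arithmetic of the five-phase model behaves as a sum, e.g. a neonatal
        threshold of 45 plus 35 stillbirths giving the phase-1 knot of 80);
        ``"exact"`` rescales neonatal deaths from livebirths to total births:
        ``sbr + nmr * (1 - sbr/1000)``.

    Returns
    -------
    Stillbirths plus neonatal deaths per 1000 total births.
    """
    if not 0 <= sbr < 1000:
        raise DomainError(f"sbr must satisfy 0 <= sbr < 1000, got {sbr}")
    if nmr < 0:
        raise DomainError(f"nmr must be >= 0, got {nmr}")
    if mode == "approximate":
        return float(sbr + nmr)
    if mode == "exact":
        return float(sbr + nmr * (1.0 - sbr / 1000.0))
    raise DomainError(f"unknown combine mode {mode!r}; expected 'exact' or 'approximate'")


def sbn_to_mmr_ratio(sbn: float, mmr: float,
                     livebirth_fraction: float = 1.0) -> float:
    """Ratio of stillbirth + neonatal deaths to maternal deaths.

    With total births approximated by livebirths the ratio reduces to
    ``100 * sbn / mmr`` (the error of the approximation is < 4% even at a
    stillbirth rate of 35 per 1000).  When livebirth counts are known,
    ``livebirth_fraction`` = livebirths / total births applies the exact
    correction.

    Raises :class:`DomainError` when ``mmr`` is 0 — use
    :func:`sbn_to_mmr_ratio_batch` for tables that may contain zeros.
    """
    if sbn < 0:
        raise DomainError(f"sbn must be >= 0, got {sbn}")
    if mmr <= 0:
        raise DomainError(f"mmr must be > 0 for a defined ratio, got {mmr}")
    if not 0 < livebirth_fraction <= 1:
        raise DomainError(
            f"livebirth_fraction must be in (0, 1], got {livebirth_fraction}")
    return 100.0 * sbn / (mmr * livebirth_fraction)


def sb_to_nn_ratio(sbr: float, nmr: float) -> float:
    """Stillbirth-to-neonatal-death ratio on a common total-births denominator.

    Stillbirths per total birth are ``sbr/1000``; neonatal deaths per total
    birth are ``(nmr/1000) * (1 - sbr/1000)``, so the ratio is
    ``sbr / (nmr * (1 - sbr/1000))``.  In the source estimates this ratio
    generally ranges from about 0.7 to 1.1.
    """
    if not 0 <= sbr < 1000:
        raise DomainError(f"sbr must satisfy 0 <= sbr < 1000, got {sbr}")
    if nmr <= 0:
        raise DomainError(f"nmr must be > 0 for a defined ratio, got {nmr}")
    return float(sbr / (nmr * (1.0 - sbr / 1000.0)))


def sbn_to_mmr_ratio_batch(sbn: np.ndarray, mmr: np.ndarray) -> np.ndarray:
    """Vectorised SBN:MMR ratio; rows with ``mmr == 0`` yield NaN and are counted."""
    sbn = np.asarray(sbn, dtype=float)
    mmr = np.asarray(mmr, dtype=float)
    if np.any(sbn < 0) or np.any(mmr < 0):
        raise DomainError("sbn and mmr must be >= 0")
    undefined = mmr == 0
    out = np.full(np.broadcast_shapes(sbn.shape, mmr.shape), np.nan)
    np.divide(100.0 * sbn, mmr, out=out, where=~undefined)
    n_undef = int(undefined.sum())
    if n_undef:
        logger.warning("sbn_to_mmr_ratio_batch: %d row(s) with mmr=0 set to NaN", n_undef)
    return out


def sb_to_nn_ratio_batch(sbr: np.ndarray, nmr: np.ndarray) -> np.ndarray:
    """Vectorised SB:NN ratio; rows with ``nmr == 0`` yield NaN and are counted."""
    sbr = np.asarray(sbr, dtype=float)
    nmr = np.asarray(nmr, dtype=float)
    if np.any(sbr < 0) or np.any(sbr >= 1000) or np.any(nmr < 0):
        raise DomainError("require 0 <= sbr < 1000 and nmr >= 0")
    undefined = nmr == 0
    denom = nmr * (1.0 - sbr / 1000.0)
    out = np.full(np.broadcast_shapes(sbr.shape, nmr.shape), np.nan)
    np.divide(sbr, denom, out=out, where=~undefined)
    n_undef = int(undefined.sum())
    if n_undef:
        logger.warning("sb_to_nn_ratio_batch: %d row(s) with nmr=0 set to NaN", n_undef)
    return out
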