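"""Registry rate statistics.

Everything a standard registry report line carries, computed from a vector
of case counts per age band and the matching person-years:

* age-specific rates ``r_i = n_i / PY_i * scale`` (scale 100,000 for
  all-ages tables, 1,000,000 for paediatric tables);
* the crude rate (total cases over total person-years);
* the directly age-standardized rate ``ASR = sum(w_i r_i) / sum(w_i)``
  against a standard population, in full or over a truncated age span
  (the truncated rate TR uses ages 35-64 by registry convention);
* cumulative rate to age 64 / 74 (percent), the cumulative risk
  ``100 (1 - exp(-cumrate/100))`` and its "one in N persons" form;
* the data-quality percentages MV% and DCO% and the M:I ratio.

Cases of unknown age enter the total count and the crude rate but are
excluded from every age-structured statistic, per standard registry
practice.  Full precision is kept internally; rounding happens only at
export time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classification import AgeBandScheme
from .demography import StandardPopulation

logger = logging.getLogger("registab")

__all__ = [
    "CountVector",
    "RateStatistics",
    "age_specific_rates",
    "crude_rate",
    "asr",
    "cumulative_rate",
    "cumulative_risk",
    "person_risk",
    "quality_percentages",
    "mi_ratio",
    "age_percent_distribution",
    "compute_rate_statistics",
    "TRUNCATED_SPAN",
]

#: Age span of the truncated rate (inclusive), registry/CI5 convention.
TRUNCATED_SPAN = (35, 64)


@dataclass
class CountVector:
    """Case counts for one stratum (site or ICCC group, one sex panel)."""

    band_counts: np.ndarray  # per age band, scheme order
    unassigned: int = 0  # unknown or out-of-scheme banding age
    mv: int = 0  # microscopically verified cases
    dco: int = 0  # death-certificate-only cases

    def __post_init__(self) -> None:
        self.band_counts = np.asarray(self.band_counts, dtype=np.int64)
        if np.any(self.band_counts < 0) or self.unassigned < 0:
            raise ValueError("negative counts")
        if not (0 <= self.mv <= self.total and 0 <= self.dco <= self.total):
            raise ValueError("MV/DCO counts exceed total")

    @property
    def total(self) -> int:
        return int(self.band_counts.sum()) + self.unassigned

    def __add__(self, other: "CountVector") -> "CountVector":
        return CountVector(
            self.band_counts + other.band_counts,
            self.unassigned + other.unassigned,
            self.mv + other.mv,
            self.dco + other.dco,
        )


@dataclass
class RateStatistics:
    """The full statistics line of an all-ages rate-table row."""

    scale: float
    age_specific: np.ndarray  # per band, NaN where person-years are zero
    crude: float
    truncated: float
    cumulative_rate_0_64: float  # percent
    cumulative_rate_0_74: float  # percent
    cumulative_risk_0_64: float  # percent
    cumulative_risk_0_74: float  # percent
    person_risk_64: int | None  # "one in N"; None when risk is zero
    person_risk_74: int | None
    asr: float
    warnings: list[str] = field(default_factory=list)


def age_specific_rates(counts: np.ndarray, person_years: np.ndarray, scale: float) -> np.ndarray:
    """Cases per band over person-years per band, scaled.

    Bands with zero person-years have no defined rate and come back NaN;
    such a band with a non-zero count is logged, and downstream weighted
    statistics skip NaN bands.
    """
    counts = np.asarray(counts, dtype=float)
    person_years = np.asarray(person_years, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(person_years > 0, counts / person_years * scale, np.nan)
    bad = (person_years == 0) & (counts > 0)
    if np.any(bad):
        logger.warning("cases present in %d band(s) with zero person-years; rate undefined", bad.sum())
    return r


def crude_rate(total_cases: float, total_person_years: float, scale: float) -> float:
    """Total cases / total person-years, scaled."""
    if total_person_years <= 0:
        raise ValueError("total person-years must be positive")
    return total_cases / total_person_years * scale


def asr(
    rates: np.ndarray,
    standard: StandardPopulation | np.ndarray,
    subset: list[int] | None = None,
) -> float:
    """Directly standardized rate: weighted mean of band rates.

    ``subset`` restricts to band indices (the truncated rate passes the
    35-64 bands; paediatric age-adjusted rates pass the 0-14 segment).
    NaN bands (zero person-years) are excluded from both sums.
    """
    weights = standard.weights if isinstance(standard, StandardPopulation) else np.asarray(standard, dtype=float)
    rates = np.asarray(rates, dtype=float)
    idx = np.arange(len(rates)) if subset is None else np.asarray(subset, dtype=int)
    if idx.size == 0:
        raise ValueError("empty band subset")
    r = rates[idx]
    w = weights[idx]
    ok = ~np.isnan(r)
    if not np.any(ok):
        return float("nan")
    return float(np.sum(w[ok] * r[ok]) / np.sum(w[ok]))


def cumulative_rate(rates: np.ndarray, scheme: AgeBandScheme, limit: int, scale: float) -> float:
    """Cumulative rate to an age limit, in percent.

    Sums band width x age-specific rate over the bands wholly below the
    limit (0-4 ... 60-64 for limit 64), i.e. for per-100,000 rates
    ``sum(5 r_i) / 1000`` percent.  The limit must align with a band edge.
    """
    idx = scheme.indices_within(0, limit)
    if not idx or scheme.bands[idx[-1]].upper != limit:
        raise ValueError(f"age limit {limit} does not align with scheme {scheme.name}")
    rates = np.asarray(rates, dtype=float)
    widths = np.asarray([scheme.bands[i].width for i in idx], dtype=float)
    r = rates[idx]
    ok = ~np.isnan(r)
    return float(100.0 * np.sum(widths[ok] * r[ok] / scale))


def cumulative_risk(cum_rate_percent: float) -> float:
    """Cumulative risk in percent: ``100 (1 - exp(-cumrate/100))``.

    The probability of developing (or dying of) the cancer before the age
    limit in the absence of competing causes of death; always below the
    cumulative rate for positive rates.
    """
    if cum_rate_percent < 0:
        raise ValueError("cumulative rate must be non-negative")
    return float(100.0 * -np.expm1(-cum_rate_percent / 100.0))


def person_risk(cum_risk_percent: float) -> int | None:
    """The 'one in N persons' form of a cumulative risk; None when risk is 0."""
    if cum_risk_percent < 0:
        raise ValueError("cumulative risk must be non-negative")
    if cum_risk_percent == 0:
        return None
    return max(1, int(round(100.0 / cum_risk_percent)))


def quality_percentages(counts: CountVector) -> tuple[float, float]:
    """(MV%, DCO%) of a stratum; (NaN, NaN) when it holds no cases."""
    if counts.total == 0:
        return (float("nan"), float("nan"))
    return (100.0 * counts.mv / counts.total, 100.0 * counts.dco / counts.total)


def mi_ratio(mortality_count: int, incidence_count: int) -> float:
    """Mortality-to-incidence ratio, a registry completeness indicator."""
    if incidence_count <= 0:
        return float("nan")
    return mortality_count / incidence_count


def age_percent_distribution(counts: CountVector) -> np.ndarray:
    """Percent of the stratum's cases falling in each band (NaN if empty)."""
    if counts.total == 0:
        return np.full(len(counts.band_counts), np.nan)
    return 100.0 * counts.band_counts / counts.total


def compute_rate_statistics(
    counts: CountVector,
    person_years: np.ndarray,
    standard: StandardPopulation,
    scheme: AgeBandScheme,
    scale: float = 100_000.0,
    truncated_span: tuple[int, int] = TRUNCATED_SPAN,
) -> RateStatistics:
    """Assemble the full all-ages statistics line for one stratum."""
    rates = age_specific_rates(counts.band_counts, person_years, scale)
    total_py = float(np.sum(person_years))
    cr64 = cumulative_rate(rates, scheme, 64, scale)
    cr74 = cumulative_rate(rates, scheme, 74, scale)
    risk64 = cumulative_risk(cr64)
    risk74 = cumulative_risk(cr74)
    warnings: list[str] = []
    if np.any(np.isnan(rates)):
        warnings.append("bands with zero person-years excluded from standardized statistics")
    return RateStatistics(
        scale=scale,
        age_specific=rates,
        crude=crude_rate(counts.total, total_py, scale),
        truncated=asr(rates, standard, scheme.indices_within(*truncated_span)),
        cumulative_rate_0_64=cr64,
        cumulative_rate_0_74=cr74,
        cumulative_risk_0_64=risk64,
        cumulative_risk_0_74=risk74,
        person_risk_64=person_risk(risk64),
        person_risk_74=person_risk(risk74),
        asr=asr(rates, standard),
        warnings=warnings,
    )
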