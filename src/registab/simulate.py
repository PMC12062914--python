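"""Synthetic registry generator.

Emits case and population CSVs in exactly the input dialect the parser
accepts, from known true rates, so the whole pipeline is testable without
any real registry export.  The mechanism is deliberately simple statistics,
not cancer natural history:

* stratum counts are Poisson with mean ``rate x person-years / 100,000``;
* ages are uniform within their band, incidence dates uniform within the
  report period;
* each case dies with the stratum's case-fatality probability after an
  exponential delay; deaths falling beyond the period end are censored and
  written with the alive sentinels (date of death 19000101, age at death
  99);
* paediatric cases draw a basis-of-diagnosis code: DCO (0) with
  probability ``p_dco``, otherwise microscopic (7) with probability
  ``p_mv / (1 - p_dco)``, otherwise clinical (1) — so the marginal MV and
  DCO probabilities equal the configured ``p_mv`` and ``p_dco``.

:func:`expected_tables` computes the statistics implied by the true rates
by direct summation, entirely independent of the rate engine, for use as
an oracle in end-to-end recovery checks.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .classification import AgeBandScheme
from .demography import world_standard

__all__ = ["StratumSpec", "SimulationSpec", "SimulatedRegistry", "simulate_registry", "expected_tables", "default_mapping_columns"]


#: Ages drawn for the open-ended 75+ band (uniform over this span).
OPEN_BAND_SPAN = 15

#: Case-file column headers emitted by the generator, per family.
_CASE_COLUMNS = {
    "all_ages": {
        "age": "AGE",
        "sex": "SEX",
        "incidence_date": "INCIDATE",
        "histology": "HIST",
        "icd10": "ICD10",
        "date_of_death": "DEATHDATE",
        "age_at_death": "AGEDEATH",
    },
    "paediatric": {
        "age": "AGE",
        "sex": "SEX",
        "incidence_date": "INCIDATE",
        "basis_of_diagnosis": "BASIS",
        "behaviour": "BEHAV",
        "iccc_code": "ICCC",
        "date_of_death": "DEATHDATE",
        "age_at_death": "AGEDEATH",
    },
}


def default_mapping_columns(family: str) -> dict[str, str]:
    """Field -> column mapping matching the generator's case-file headers."""
    return dict(_CASE_COLUMNS[family])


@dataclass(frozen=True)
class StratumSpec:
    """True incidence rates for one (site or ICCC code) x sex stratum."""

    code: str  # ICD-10 token ("C50") or ICCC token ("Ia")
    sex: str  # "male" | "female"
    rates: np.ndarray  # per 100,000 person-years, one entry per band

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class SimulationSpec:
    family: str  # "all_ages" | "paediatric"
    scheme: AgeBandScheme
    years: tuple[int, int]  # inclusive report period
    strata: tuple[StratumSpec, ...]
    population: dict[str, np.ndarray]  # person-years per band over the whole period
    case_fatality: float = 0.3
    death_delay_mean_days: float = 365.0
    p_mv: float = 0.85
    p_dco: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _CASE_COLUMNS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.years[0] > self.years[1]:
            raise ValueError("years out of order")
        for p in (self.case_fatality, self.p_mv, self.p_dco):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_mv + self.p_dco > 1.0:
            raise ValueError("p_mv + p_dco must not exceed 1")
        for s in self.strata:
            if len(s.rates) != len(self.scheme):
                raise ValueError(f"stratum {s.code}/{s.sex}: rates do not cover every band")
            if s.sex not in self.population:
                raise ValueError(f"stratum {s.code}/{s.sex}: no population for that sex")
        for sex, py in self.population.items():
            if len(py) != len(self.scheme) or np.any(np.asarray(py) < 0):
                raise ValueError(f"bad person-years vector for {sex!r}")


@dataclass
class SimulatedRegistry:
    case_csv: str
    population_csv: str
    truth: dict = field(default_factory=dict)


def simulate_registry(spec: SimulationSpec) -> SimulatedRegistry:
    """Draw a synthetic registry; identical spec (incl. seed) gives identical bytes."""
    rng = np.random.default_rng(spec.seed)
    start = date(spec.years[0], 1, 1)
    end = date(spec.years[1], 12, 31)
    n_days = (end - start).days + 1
    sex_code = {"male": 1, "female": 2}

    rows: list[list[str]] = []
    observed: dict[tuple[str, str], np.ndarray] = {}
    observed_mv: dict[tuple[str, str], int] = {}
    observed_dco: dict[tuple[str, str], int] = {}
    observed_deaths_in_period: dict[tuple[str, str], int] = {}

    for stratum in spec.strata:
        py = np.asarray(spec.population[stratum.sex], dtype=float)
        means = stratum.rates * py / 100_000.0
        counts = rng.poisson(means)
        observed[(stratum.code, stratum.sex)] = counts
        mv_n = dco_n = deaths = 0
        for band_idx, n in enumerate(counts):
            band = spec.scheme.bands[band_idx]
            hi = band.upper if band.upper is not None else band.lower + OPEN_BAND_SPAN - 1
            for _ in range(int(n)):
                age = int(rng.integers(band.lower, hi + 1))
                inc = start + timedelta(days=int(rng.integers(0, n_days)))
                dies = rng.random() < spec.case_fatality
                death_date = None
                if dies:
                    delay = rng.exponential(spec.death_delay_mean_days)
                    candidate = inc + timedelta(days=int(delay))
                    if candidate <= end:  # deaths past period end are censored
                        death_date = candidate
                if death_date is None:
                    dd, aad = "19000101", "99"
                else:
                    deaths += 1
                    dd = death_date.strftime("%Y%m%d")
                    aad = str(min(98, age + int((death_date - inc).days / 365.25)))
                row = [str(age), str(sex_code[stratum.sex]), inc.strftime("%Y%m%d")]
                if spec.family == "all_ages":
                    row += ["8000", stratum.code, dd, aad]
                else:
                    u = rng.random()
                    if u < spec.p_dco:
                        basis = 0
                        dco_n += 1
                    elif u < spec.p_dco + spec.p_mv:
                        basis = 7
                        mv_n += 1
                    else:
                        basis = 1
                    row += [str(basis), "3", stratum.code, dd, aad]
                rows.append(row)
        observed_mv[(stratum.code, stratum.sex)] = mv_n
        observed_dco[(stratum.code, stratum.sex)] = dco_n
        observed_deaths_in_period[(stratum.code, stratum.sex)] = deaths

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(list(_CASE_COLUMNS[spec.family].values()))
    writer.writerows(rows)

    pop_buf = io.StringIO()
    pop_writer = csv.writer(pop_buf, lineterminator="\n")
    sexes = [s for s in ("male", "female") if s in spec.population]
    pop_writer.writerow(["ageband"] + sexes)
    for i, band in enumerate(spec.scheme.bands):
        pop_writer.writerow([band.label] + [f"{spec.population[s][i]:.0f}" for s in sexes])

    truth = {
        "observed_counts": observed,
        "observed_mv": observed_mv,
        "observed_dco": observed_dco,
        "observed_deaths_in_period": observed_deaths_in_period,
        "expected": expected_tables(spec),
    }
    return SimulatedRegistry(buf.getvalue(), pop_buf.getvalue(), truth)


def expected_tables(spec: SimulationSpec) -> dict:
    """Closed-form expected statistics per stratum, by direct summation.

    Independent of the rate engine: every quantity below is computed with
    explicit loops over bands from the true rates and person-years.
    """
    std = world_standard(spec.scheme)
    out: dict[tuple[str, str], dict] = {}
    for stratum in spec.strata:
        py = np.asarray(spec.population[stratum.sex], dtype=float)
        rates = stratum.rates
        expected_counts = [rates[i] * py[i] / 100_000.0 for i in range(len(py))]
        total_py = sum(py)
        crude = sum(expected_counts) / total_py * 100_000.0 if total_py else float("nan")

        num = den = 0.0
        for i in range(len(rates)):
            num += std.weights[i] * rates[i]
            den += std.weights[i]
        asr_expected = num / den

        cum: dict[int, float] = {}
        for limit in (14, 19, 64, 74):
            acc = 0.0
            ok = False
            for i, band in enumerate(spec.scheme.bands):
                if band.upper is not None and band.upper <= limit:
                    acc += band.width * rates[i] / 100_000.0
                    ok = ok or band.upper == limit
            if ok:
                cum[limit] = 100.0 * acc
        risks = {k: 100.0 * (1.0 - math.exp(-v / 100.0)) for k, v in cum.items()}

        out[(stratum.code, stratum.sex)] = {
            "expected_counts": expected_counts,
            "age_specific": list(rates),
            "crude": crude,
            "asr": asr_expected,
            "cumulative_rate": cum,
            "cumulative_risk": risks,
            "mv_percent": 100.0 * spec.p_mv,
            "dco_percent": 100.0 * spec.p_dco,
        }
    return out
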