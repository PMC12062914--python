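"""Population denominators and standard populations.

The denominator for every rate is person-years by sex and age band,
supplied as a small CSV (header ``ageband,male,female`` or
``ageband,population`` for both-sex tables).  For a report period spanning
several calendar years the file must already hold the summed person-years
of the period — the engine performs no interpolation; :func:`sum_periods`
exists so single-year files can be combined.

Direct age standardization uses the Segi (1960) world standard population
(weights summing to 100,000), shipped as data and collapsible onto any of
the three banding schemes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np

from .classification import ALL_AGES_16, PAED_4, PAED_5_ZERO, AgeBandScheme, _read_data_csv

__all__ = [
    "PopulationDataset",
    "StandardPopulation",
    "PopulationFormatError",
    "parse_population_csv",
    "sum_periods",
    "world_standard",
]


class PopulationFormatError(ValueError):
    """Population CSV does not conform to the dialect."""


@dataclass(frozen=True)
class PopulationDataset:
    """Person-years by sex and age band over one report period.

    ``person_years`` is keyed by ``"male"``, ``"female"`` and/or ``"both"``;
    each vector covers every band of the scheme, in scheme order.
    """

    scheme: AgeBandScheme
    person_years: dict[str, np.ndarray]
    period: str = ""

    def __post_init__(self) -> None:
        for sex, vec in self.person_years.items():
            if sex not in ("male", "female", "both"):
                raise PopulationFormatError(f"unknown sex key {sex!r}")
            if len(vec) != len(self.scheme):
                raise PopulationFormatError(f"{sex} person-years do not cover every band")
            if np.any(np.asarray(vec) < 0):
                raise PopulationFormatError("negative person-years")

    def sex_vector(self, sex: str) -> np.ndarray:
        """Person-years per band for "male", "female" or "both" (pooled)."""
        if sex in self.person_years:
            return self.person_years[sex]
        if sex == "both" and {"male", "female"} <= self.person_years.keys():
            return self.person_years["male"] + self.person_years["female"]
        raise PopulationFormatError(f"population file carries no {sex!r} person-years")


def parse_population_csv(raw: str, scheme: AgeBandScheme, period: str = "") -> PopulationDataset:
    """Parse a population CSV onto a band scheme.

    Band labels are matched case-insensitively against the scheme labels;
    every band must be present exactly once per sex column.
    """
    reader = csv.reader(io.StringIO(raw.lstrip("﻿")))
    rows = [r for r in reader if r and any(cell.strip() for cell in r)]
    if not rows:
        raise PopulationFormatError("empty population file")
    header = [h.strip().lower() for h in rows[0]]
    if not header or header[0] not in ("ageband", "age band", "band"):
        raise PopulationFormatError("first column must be the age band")
    sex_cols = header[1:]
    if sex_cols == ["population"]:
        sex_keys = ["both"]
    elif set(sex_cols) <= {"male", "female"} and sex_cols:
        sex_keys = sex_cols
    else:
        raise PopulationFormatError(
            "population columns must be 'male'/'female' or a single 'population' column"
        )

    vectors = {k: np.full(len(scheme), np.nan) for k in sex_keys}
    for rowno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise PopulationFormatError(f"row {rowno}: expected {len(header)} cells")
        try:
            band = scheme.index_of(row[0])
        except KeyError:
            raise PopulationFormatError(
                f"row {rowno}: band {row[0]!r} not in scheme {scheme.name}"
            ) from None
        for key, cell in zip(sex_keys, row[1:]):
            try:
                py = float(cell)
            except ValueError:
                raise PopulationFormatError(f"row {rowno}: non-numeric person-years {cell!r}") from None
            if py < 0:
                raise PopulationFormatError(f"row {rowno}: negative person-years")
            if not np.isnan(vectors[key][band]):
                raise PopulationFormatError(f"row {rowno}: duplicate band {row[0]!r}")
            vectors[key][band] = py
    for key, vec in vectors.items():
        missing = np.flatnonzero(np.isnan(vec))
        if missing.size:
            raise PopulationFormatError(f"band {scheme.bands[missing[0]].label!r} absent")
    return PopulationDataset(scheme, vectors, period)


def sum_periods(datasets: list[PopulationDataset]) -> PopulationDataset:
    """Entrywise sum of person-years over report years sharing one scheme."""
    if not datasets:
        raise ValueError("no datasets to sum")
    first = datasets[0]
    keys = set(first.person_years)
    for d in datasets[1:]:
        if d.scheme is not first.scheme and d.scheme != first.scheme:
            raise ValueError("datasets use different band schemes")
        if set(d.person_years) != keys:
            raise ValueError("datasets cover different sexes")
    summed = {k: np.sum([d.person_years[k] for d in datasets], axis=0) for k in keys}
    period = "+".join(d.period for d in datasets if d.period)
    return PopulationDataset(first.scheme, summed, period)


@dataclass(frozen=True)
class StandardPopulation:
    """Age weights for direct standardization, on one band scheme."""

    name: str
    scheme: AgeBandScheme
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.scheme):
            raise ValueError("weights do not cover every band")
        if np.any(self.weights <= 0):
            raise ValueError("standard weights must be positive")

    @property
    def total(self) -> float:
        return float(np.sum(self.weights))


_SEGI_CACHE: dict[str, StandardPopulation] = {}

#: Fraction of the Segi 0-4 weight assigned to the single-year age-0 band
#: when collapsing onto PAED_5_ZERO (uniform single-year assumption, 1:4).
AGE_ZERO_SPLIT = 0.2


def world_standard(scheme: AgeBandScheme) -> StandardPopulation:
    """Segi world-standard weights collapsed onto a supported band scheme.

    75+ pools the published 75-79, 80-84 and 85+ weights; the paediatric
    schemes take the 0-19 segment, with the 0-4 weight split 1:4 between
    age 0 and ages 1-4 for the separate-zero scheme.
    """
    if scheme.name in _SEGI_CACHE:
        return _SEGI_CACHE[scheme.name]
    rows = _read_data_csv("segi_world.csv")
    by_band = {r["band"]: float(r["weight"]) for r in rows}
    if scheme is ALL_AGES_16 or scheme == ALL_AGES_16:
        weights = [by_band[b.label] for b in scheme.bands[:-1]]
        weights.append(by_band["75-79"] + by_band["80-84"] + by_band["85+"])
    elif scheme == PAED_4:
        weights = [by_band[b.label] for b in scheme.bands]
    elif scheme == PAED_5_ZERO:
        w04 = by_band["0-4"]
        weights = [AGE_ZERO_SPLIT * w04, (1 - AGE_ZERO_SPLIT) * w04, by_band["5-9"], by_band["10-14"], by_band["15-19"]]
    else:
        raise ValueError(f"no world-standard weights for scheme {scheme.name!r}")
    std = StandardPopulation("Segi world standard", scheme, np.asarray(weights, dtype=float))
    _SEGI_CACHE[scheme.name] = std
    return std
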