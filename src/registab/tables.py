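"""Table assembly: the eight registry table types.

All-ages family (one sex per table, 5-year bands 0-4 ... 75+):

* incidence / mortality **counts** by age group (no denominator needed);
* incidence / mortality **rates** per 100,000 by age group, each site row
  carrying the full statistics line (crude, TR, cumulative rate/risk to
  64 and 74, person risk, ASR).

Paediatric family (ICCC-3, ages 0-19 at incidence, rates per million):
both-sex or by-sex panels, with or without a separate single-year age-0
band.  Rows follow the ICCC-3 order — each of the 12 main groups followed
by its subgroups (47 in total); a main-group row counts its own
main-only-coded cases plus all subgroup-coded ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .classification import (
    ALL_AGES_16,
    PAED_4,
    PAED_5_ZERO,
    AgeBandScheme,
    BasisCodeTable,
    ICCCScheme,
    SiteGroupScheme,
    load_basis_codes,
    load_iccc,
    load_site_groups,
)
from .demography import PopulationDataset, StandardPopulation, world_standard
from .rates import (
    CountVector,
    RateStatistics,
    age_percent_distribution,
    age_specific_rates,
    asr,
    compute_rate_statistics,
    quality_percentages,
)
from .registry_io import FEMALE, MALE, RegistryRecord

logger = logging.getLogger("registab")

__all__ = [
    "TableType",
    "RateTableRow",
    "AllAgesTable",
    "PaediatricTableRow",
    "PaediatricPanel",
    "PaediatricTable",
    "tabulate_counts",
    "build_all_ages_table",
    "build_paediatric_table",
]

_SEX_CODE = {"male": MALE, "female": FEMALE}


class TableType(Enum):
    """The eight table types, named as on the command line."""

    INCIDENCE_COUNTS = "incidence-counts"
    INCIDENCE_RATES = "incidence-rates"
    MORTALITY_COUNTS = "mortality-counts"
    MORTALITY_RATES = "mortality-rates"
    PAED_BOTH = "paed-both"
    PAED_BY_SEX = "paed-by-sex"
    PAED_BOTH_ZERO = "paed-both-zero"
    PAED_BY_SEX_ZERO = "paed-by-sex-zero"

    @property
    def family(self) -> str:
        return "all_ages" if self.value.split("-")[0] in ("incidence", "mortality") else "paediatric"

    @property
    def basis(self) -> str:
        """Which date field the period filter applies to."""
        return "mortality" if self.value.startswith("mortality") else "incidence"

    @property
    def rates(self) -> bool:
        """Whether the table carries rate columns (needs a denominator)."""
        return self.value.endswith("rates") or self.family == "paediatric"

    @property
    def by_sex(self) -> bool:
        return "by-sex" in self.value

    @property
    def zero_band(self) -> bool:
        return self.value.endswith("zero")

    @property
    def band_scheme(self) -> AgeBandScheme:
        if self.family == "all_ages":
            return ALL_AGES_16
        return PAED_5_ZERO if self.zero_band else PAED_4


# ---------------------------------------------------------------------------
# Counting


@dataclass
class AllAgesCounts:
    per_site: list[CountVector]
    all_sites: CountVector
    excluded_non_neoplasm: int  # records whose code is outside C00-C97


@dataclass
class PaediatricCounts:
    per_main: list[CountVector]
    per_sub: list[list[CountVector]]  # parallel to scheme.main_groups[i].subgroups
    unclassified: CountVector
    excluded: int  # out-of-age-range or filtered-behaviour records


def _banding_age(record: RegistryRecord, basis: str) -> int | None:
    return record.age if basis == "incidence" else record.age_at_death


def tabulate_counts(
    records: list[RegistryRecord],
    scheme: SiteGroupScheme | ICCCScheme,
    band_scheme: AgeBandScheme,
    sex: str | None = None,
    basis: str = "incidence",
    basis_codes: BasisCodeTable | None = None,
    include_behaviours: tuple[int, ...] = (3,),
) -> AllAgesCounts | PaediatricCounts:
    """Count period-filtered records into stratum x age-band cells.

    Incidence tables band by age at incidence, mortality tables by age at
    death (unknown -> the unassigned column).  ``sex`` of "male"/"female"
    restricts to that sex; None pools both.  Dispatches on the scheme kind.
    """
    if sex is not None:
        code = _SEX_CODE[sex]
        records = [r for r in records if r.sex == code]
    if isinstance(scheme, SiteGroupScheme):
        return _tabulate_all_ages(records, scheme, band_scheme, basis)
    return _tabulate_paediatric(records, scheme, band_scheme, basis_codes or load_basis_codes(), include_behaviours)


def _tabulate_all_ages(
    records: list[RegistryRecord],
    scheme: SiteGroupScheme,
    band_scheme: AgeBandScheme,
    basis: str,
) -> AllAgesCounts:
    n_bands = len(band_scheme)
    site_counts = np.zeros((len(scheme), n_bands), dtype=np.int64)
    site_unassigned = np.zeros(len(scheme), dtype=np.int64)
    excluded = 0
    for r in records:
        site = scheme.assign(r.icd10 or "")
        if site is None:
            excluded += 1
            continue
        band = band_scheme.assign(_banding_age(r, basis))
        if band is None:
            site_unassigned[site] += 1
        else:
            site_counts[site, band] += 1
    per_site = [CountVector(site_counts[i], int(site_unassigned[i])) for i in range(len(scheme))]
    all_sites = CountVector(site_counts.sum(axis=0), int(site_unassigned.sum()))
    if excluded:
        logger.warning("%d record(s) with non-neoplasm codes excluded from site rows", excluded)
    return AllAgesCounts(per_site, all_sites, excluded)


def _tabulate_paediatric(
    records: list[RegistryRecord],
    scheme: ICCCScheme,
    band_scheme: AgeBandScheme,
    basis_codes: BasisCodeTable,
    include_behaviours: tuple[int, ...],
) -> PaediatricCounts:
    n_bands = len(band_scheme)

    def blank() -> CountVector:
        return CountVector(np.zeros(n_bands, dtype=np.int64))

    per_main = [blank() for _ in scheme.main_groups]
    per_sub = [[blank() for _ in m.subgroups] for m in scheme.main_groups]
    unclassified = blank()
    excluded = 0

    for r in records:
        if r.age > 19 or (r.behaviour is not None and r.behaviour not in include_behaviours):
            excluded += 1
            continue
        band = band_scheme.assign(r.age)  # paediatric eligibility is age at incidence
        mv = int(basis_codes.is_microscopically_verified(r.basis_of_diagnosis)) if r.basis_of_diagnosis is not None else 0
        dco = int(basis_codes.is_dco(r.basis_of_diagnosis)) if r.basis_of_diagnosis is not None else 0
        hit = scheme.lookup(r.iccc_code or "")
        targets: list[CountVector]
        if hit is None:
            logger.warning("unclassified ICCC code %r", r.iccc_code)
            targets = [unclassified]
        else:
            mi, si = hit
            targets = [per_main[mi]] + ([per_sub[mi][si]] if si is not None else [])
        for cv in targets:
            if band is None:
                cv.unassigned += 1
            else:
                cv.band_counts[band] += 1
            cv.mv += mv
            cv.dco += dco
    if excluded:
        logger.info("%d record(s) outside ages 0-19 or filtered behaviour excluded", excluded)
    return PaediatricCounts(per_main, per_sub, unclassified, excluded)


# ---------------------------------------------------------------------------
# All-ages tables


@dataclass
class RateTableRow:
    label: str
    codes: str
    counts: CountVector
    stats: RateStatistics | None = None


@dataclass
class AllAgesTable:
    table_type: TableType
    sex: str
    band_scheme: AgeBandScheme
    rows: list[RateTableRow]  # one per site entry, scheme order
    all_sites: RateTableRow
    excluded_non_neoplasm: int
    period: str = ""

    def to_dataframe(self):
        """Counts (and summary statistics for rate tables) as a DataFrame."""
        import pandas as pd

        data = []
        for row in self.rows + [self.all_sites]:
            d: dict[str, object] = {"site": row.label, "icd10": row.codes}
            if self.table_type.rates and row.stats is not None:
                d.update(zip(self.band_scheme.labels, row.stats.age_specific))
                d.update(
                    cases=row.counts.total,
                    crude=row.stats.crude,
                    tr=row.stats.truncated,
                    cum_rate_0_64=row.stats.cumulative_rate_0_64,
                    cum_rate_0_74=row.stats.cumulative_rate_0_74,
                    cum_risk_0_64=row.stats.cumulative_risk_0_64,
                    cum_risk_0_74=row.stats.cumulative_risk_0_74,
                    asr=row.stats.asr,
                )
            else:
                d.update(zip(self.band_scheme.labels, row.counts.band_counts))
                d.update(unknown_age=row.counts.unassigned, total=row.counts.total)
            data.append(d)
        return pd.DataFrame(data)


def build_all_ages_table(
    table_type: TableType,
    records: list[RegistryRecord],
    population: PopulationDataset | None = None,
    standard: StandardPopulation | None = None,
    sex: str = "male",
    site_scheme: SiteGroupScheme | None = None,
    period: str = "",
) -> AllAgesTable:
    """Build one all-ages table from period-filtered records.

    Count variants need no denominator; rate variants require a population
    covering the selected sex and standardize against the Segi world
    standard unless another standard is supplied.
    """
    if table_type.family != "all_ages":
        raise ValueError(f"{table_type} is not an all-ages table type")
    if sex not in _SEX_CODE:
        raise ValueError("all-ages tables require sex 'male' or 'female'")
    scheme = site_scheme or load_site_groups()
    band_scheme = table_type.band_scheme
    counted = tabulate_counts(records, scheme, band_scheme, sex=sex, basis=table_type.basis)
    assert isinstance(counted, AllAgesCounts)

    py = std = None
    if table_type.rates:
        if population is None:
            raise ValueError("rate tables require a population dataset")
        if population.scheme != band_scheme:
            raise ValueError("population dataset is not on the all-ages band scheme")
        py = population.sex_vector(sex)
        std = standard or world_standard(band_scheme)

    def make_row(entry_label: str, codes: str, cv: CountVector) -> RateTableRow:
        stats = None
        if table_type.rates:
            stats = compute_rate_statistics(cv, py, std, band_scheme, scale=100_000.0)
        return RateTableRow(entry_label, codes, cv, stats)

    rows = [
        make_row(e.label, e.codes_spec, cv)
        for e, cv in zip(scheme.entries, counted.per_site)
    ]
    all_sites = make_row("All sites", "C00-C97", counted.all_sites)
    return AllAgesTable(table_type, sex, band_scheme, rows, all_sites, counted.excluded_non_neoplasm, period)


# ---------------------------------------------------------------------------
# Paediatric tables


@dataclass
class PaediatricTableRow:
    code: str
    label: str
    is_subgroup: bool
    counts: CountVector
    total_0_14: int
    total_0_19: int
    percent_by_band: np.ndarray
    rates_by_band: np.ndarray | None  # per million; None in counts-only tables
    aar_0_14: float | None
    aar_0_19: float | None
    mv_percent: float
    dco_percent: float


@dataclass
class PaediatricPanel:
    sex: str  # "both", "male" or "female"
    rows: list[PaediatricTableRow]
    unclassified: PaediatricTableRow | None
    excluded: int


@dataclass
class PaediatricTable:
    table_type: TableType
    band_scheme: AgeBandScheme
    panels: list[PaediatricPanel]
    period: str = ""

    def to_dataframe(self):
        import pandas as pd

        data = []
        for panel in self.panels:
            for row in panel.rows:
                d: dict[str, object] = {"panel": panel.sex, "iccc": row.code, "group": row.label}
                d.update(zip(self.band_scheme.labels, row.counts.band_counts))
                d.update(total_0_14=row.total_0_14, total_0_19=row.total_0_19)
                if row.rates_by_band is not None:
                    d.update({f"rate {b}": r for b, r in zip(self.band_scheme.labels, row.rates_by_band)})
                d.update(aar_0_14=row.aar_0_14, aar_0_19=row.aar_0_19, mv_pct=row.mv_percent, dco_pct=row.dco_percent)
                data.append(d)
        return pd.DataFrame(data)


def build_paediatric_table(
    table_type: TableType,
    records: list[RegistryRecord],
    population: PopulationDataset | None = None,
    standard: StandardPopulation | None = None,
    iccc_scheme: ICCCScheme | None = None,
    basis_codes: BasisCodeTable | None = None,
    include_behaviours: tuple[int, ...] = (3,),
    period: str = "",
) -> PaediatricTable:
    """Build one paediatric ICCC-3 table (rates per million when a
    denominator is supplied; counts-only otherwise)."""
    if table_type.family != "paediatric":
        raise ValueError(f"{table_type} is not a paediatric table type")
    scheme = iccc_scheme or load_iccc()
    band_scheme = table_type.band_scheme
    if population is not None and population.scheme != band_scheme:
        raise ValueError(
            f"population dataset must use bands {band_scheme.labels} "
            f"(the {'separate-zero ' if table_type.zero_band else ''}paediatric scheme)"
        )
    std = standard or world_standard(band_scheme)
    idx_0_14 = band_scheme.indices_within(0, 14)

    panels: list[PaediatricPanel] = []
    for panel_sex in (("male", "female") if table_type.by_sex else ("both",)):
        counted = tabulate_counts(
            records,
            scheme,
            band_scheme,
            sex=None if panel_sex == "both" else panel_sex,
            basis="incidence",
            basis_codes=basis_codes,
            include_behaviours=include_behaviours,
        )
        assert isinstance(counted, PaediatricCounts)
        py = population.sex_vector(panel_sex) if population is not None else None

        def make_row(code: str, label: str, is_sub: bool, cv: CountVector) -> PaediatricTableRow:
            rates = aar14 = aar19 = None
            if py is not None:
                rates = age_specific_rates(cv.band_counts, py, 1_000_000.0)
                aar14 = asr(rates, std, idx_0_14)
                aar19 = asr(rates, std)
            mv_pct, dco_pct = quality_percentages(cv)
            return PaediatricTableRow(
                code,
                label,
                is_sub,
                cv,
                total_0_14=int(cv.band_counts[idx_0_14].sum()),
                total_0_19=int(cv.band_counts.sum()),
                percent_by_band=age_percent_distribution(cv),
                rates_by_band=rates,
                aar_0_14=aar14,
                aar_0_19=aar19,
                mv_percent=mv_pct,
                dco_percent=dco_pct,
            )

        rows: list[PaediatricTableRow] = []
        for mi, main in enumerate(scheme.main_groups):
            rows.append(make_row(main.code, main.label, False, counted.per_main[mi]))
            for si, sub in enumerate(main.subgroups):
                rows.append(make_row(sub.code, sub.label, True, counted.per_sub[mi][si]))
        unclassified = None
        if counted.unclassified.total > 0:
            unclassified = make_row("UNCL", "Unclassified ICCC codes", False, counted.unclassified)
        panels.append(PaediatricPanel(panel_sex, rows, unclassified, counted.excluded))
    return PaediatricTable(table_type, band_scheme, panels, period)
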