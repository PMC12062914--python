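"""Table assembly: structure, conservation and banding semantics."""

from datetime import date

import numpy as np
import pytest

from registab.classification import ALL_AGES_16, PAED_4, PAED_5_ZERO
from registab.demography import parse_population_csv
from registab.rates import compute_rate_statistics
from registab.registry_io import FEMALE, MALE, RegistryRecord, filter_by_period
from registab.tables import (
    AllAgesCounts,
    TableType,
    build_all_ages_table,
    build_paediatric_table,
    tabulate_counts,
)


def rec(age=42, sex=FEMALE, icd10="C50", inc=date(2018, 3, 15), dod=None, aad=None):
    return RegistryRecord(age, sex, inc, dod, aad, icd10=icd10, histology="8140")


def paed_rec(age=4, sex=MALE, iccc="Ia", basis=7, behaviour=3, inc=date(2018, 6, 1)):
    return RegistryRecord(
        age, sex, inc, None, None, basis_of_diagnosis=basis, behaviour=behaviour, iccc_code=iccc
    )


class TestTableType:
    def test_families_and_bases(self):
        assert TableType.MORTALITY_RATES.family == "all_ages"
        assert TableType.MORTALITY_RATES.basis == "mortality"
        assert TableType.PAED_BY_SEX_ZERO.family == "paediatric"
        assert TableType.PAED_BY_SEX_ZERO.basis == "incidence"

    def test_band_schemes(self):
        assert TableType.INCIDENCE_COUNTS.band_scheme is ALL_AGES_16
        assert TableType.PAED_BOTH.band_scheme is PAED_4
        assert TableType.PAED_BOTH_ZERO.band_scheme is PAED_5_ZERO

    def test_counts_variants_need_no_denominator(self):
        assert not TableType.INCIDENCE_COUNTS.rates
        assert not TableType.MORTALITY_COUNTS.rates
        assert TableType.PAED_BOTH.rates


class TestTabulateCounts:
    def test_single_record_trace(self, site_scheme):
        counted = tabulate_counts([rec(age=42)], site_scheme, ALL_AGES_16, sex="female")
        breast = next(i for i, e in enumerate(site_scheme.entries) if e.label == "Breast")
        band = ALL_AGES_16.index_of("40-44")
        assert counted.per_site[breast].band_counts[band] == 1
        assert counted.all_sites.band_counts[band] == 1
        assert counted.all_sites.total == 1

    def test_mortality_bands_by_age_at_death(self, site_scheme):
        r = rec(age=42, dod=date(2019, 7, 1), aad=45)
        inc = tabulate_counts([r], site_scheme, ALL_AGES_16, sex="female", basis="incidence")
        mort = tabulate_counts([r], site_scheme, ALL_AGES_16, sex="female", basis="mortality")
        breast = next(i for i, e in enumerate(site_scheme.entries) if e.label == "Breast")
        assert inc.per_site[breast].band_counts[ALL_AGES_16.index_of("40-44")] == 1
        assert mort.per_site[breast].band_counts[ALL_AGES_16.index_of("45-49")] == 1

    def test_unknown_age_at_death_goes_to_unassigned(self, site_scheme):
        r = rec(dod=date(2019, 7, 1), aad=None)
        counted = tabulate_counts([r], site_scheme, ALL_AGES_16, sex="female", basis="mortality")
        assert counted.all_sites.unassigned == 1
        assert counted.all_sites.band_counts.sum() == 0

    def test_empty_records_give_all_zero(self, site_scheme):
        counted = tabulate_counts([], site_scheme, ALL_AGES_16, sex="male")
        assert counted.all_sites.total == 0

    def test_non_neoplasm_excluded_and_counted(self, site_scheme):
        counted = tabulate_counts([rec(icd10="K35")], site_scheme, ALL_AGES_16, sex="female")
        assert isinstance(counted, AllAgesCounts)
        assert counted.excluded_non_neoplasm == 1
        assert counted.all_sites.total == 0


class TestAllAgesTable:
    def test_exactly_53_site_rows(self, filtered_allages, allages_sim):
        t = build_all_ages_table(
            TableType.INCIDENCE_RATES, filtered_allages, allages_sim.population, sex="female"
        )
        assert len(t.rows) == 53
        assert t.all_sites.label == "All sites"

    def test_counts_variant_runs_without_population(self, filtered_allages):
        t = build_all_ages_table(TableType.INCIDENCE_COUNTS, filtered_allages, sex="female")
        assert t.rows[0].stats is None
        assert t.all_sites.counts.total > 0

    def test_rate_variant_requires_population(self, filtered_allages):
        with pytest.raises(ValueError, match="population"):
            build_all_ages_table(TableType.INCIDENCE_RATES, filtered_allages, sex="female")

    def test_all_sites_conserves_filtered_neoplasm_records(self, allages_sim, site_scheme):
        kept = filter_by_period(allages_sim.records, "incidence", *allages_sim.period)
        for sex, code in (("female", FEMALE), ("male", MALE)):
            t = build_all_ages_table(TableType.INCIDENCE_COUNTS, kept, sex=sex)
            expected = sum(1 for r in kept if r.sex == code and site_scheme.assign(r.icd10) is not None)
            assert t.all_sites.counts.total == expected
            assert sum(row.counts.total for row in t.rows) == expected

    def test_row_statistics_equal_rate_engine_on_row_counts(self, filtered_allages, allages_sim, segi16):
        t = build_all_ages_table(
            TableType.INCIDENCE_RATES, filtered_allages, allages_sim.population, sex="female"
        )
        row = next(r for r in t.rows if r.label == "Breast")
        py = allages_sim.population.sex_vector("female")
        expected = compute_rate_statistics(row.counts, py, segi16, ALL_AGES_16)
        assert row.stats.crude == pytest.approx(expected.crude)
        assert row.stats.asr == pytest.approx(expected.asr)
        assert np.allclose(row.stats.age_specific, expected.age_specific, equal_nan=True)

    def test_rate_and_count_tables_share_count_cells(self, filtered_allages, allages_sim):
        tr = build_all_ages_table(
            TableType.INCIDENCE_RATES, filtered_allages, allages_sim.population, sex="female"
        )
        tc = build_all_ages_table(TableType.INCIDENCE_COUNTS, filtered_allages, sex="female")
        for a, b in zip(tr.rows, tc.rows):
            assert np.array_equal(a.counts.band_counts, b.counts.band_counts)

    def test_mortality_table_from_same_records(self, allages_sim):
        kept = filter_by_period(allages_sim.records, "mortality", *allages_sim.period)
        t = build_all_ages_table(TableType.MORTALITY_COUNTS, kept, sex="male")
        assert t.all_sites.counts.total == len([r for r in kept if r.sex == MALE])

    def test_sex_selector_required(self, filtered_allages):
        with pytest.raises(ValueError, match="sex"):
            build_all_ages_table(TableType.INCIDENCE_COUNTS, filtered_allages, sex="both")


class TestPaediatricTable:
    def test_12_main_and_47_subgroup_rows(self, filtered_paed, paed_sim):
        t = build_paediatric_table(TableType.PAED_BOTH, filtered_paed, paed_sim.population)
        rows = t.panels[0].rows
        assert sum(1 for r in rows if not r.is_subgroup) == 12
        assert sum(1 for r in rows if r.is_subgroup) == 47

    def test_rows_in_iccc_order_mains_before_their_subs(self, filtered_paed, paed_sim, iccc_scheme):
        t = build_paediatric_table(TableType.PAED_BOTH, filtered_paed, paed_sim.population)
        codes = [r.code for r in t.panels[0].rows]
        expected = []
        for m in iccc_scheme.main_groups:
            expected.append(m.code)
            expected.extend(s.code for s in m.subgroups)
        assert codes == expected

    def test_main_rows_cover_subgroup_and_main_only_cases(self):
        records = [paed_rec(iccc="Ia"), paed_rec(iccc="Ib"), paed_rec(iccc="I")]
        t = build_paediatric_table(TableType.PAED_BOTH, records)
        rows = {r.code: r for r in t.panels[0].rows}
        assert rows["I"].total_0_19 == 3
        assert rows["Ia"].total_0_19 == 1
        assert rows["Ib"].total_0_19 == 1

    def test_zero_variant_separate_age_zero_band(self):
        records = [paed_rec(age=0, iccc="Ia"), paed_rec(age=4, iccc="Ia")]
        t = build_paediatric_table(TableType.PAED_BOTH_ZERO, records)
        row = next(r for r in t.panels[0].rows if r.code == "Ia")
        assert row.counts.band_counts[PAED_5_ZERO.index_of("0")] == 1
        assert row.counts.band_counts[PAED_5_ZERO.index_of("1-4")] == 1

    def test_zero_variant_rejects_population_without_age_zero_band(self, filtered_paed, paed_sim):
        with pytest.raises(ValueError, match="separate-zero"):
            build_paediatric_table(TableType.PAED_BOTH_ZERO, filtered_paed, paed_sim.population)

    def test_sex_panels_sum_to_both_sex_table(self, filtered_paed, paed_sim):
        both = build_paediatric_table(TableType.PAED_BOTH, filtered_paed, paed_sim.population)
        by_sex = build_paediatric_table(TableType.PAED_BY_SEX, filtered_paed, paed_sim.population)
        assert [p.sex for p in by_sex.panels] == ["male", "female"]
        for i, row in enumerate(both.panels[0].rows):
            split = [p.rows[i] for p in by_sex.panels]
            assert row.total_0_19 == sum(r.total_0_19 for r in split)
            assert np.array_equal(
                row.counts.band_counts, split[0].counts.band_counts + split[1].counts.band_counts
            )

    def test_0_19_total_is_0_14_plus_adolescents(self, filtered_paed, paed_sim):
        t = build_paediatric_table(TableType.PAED_BOTH, filtered_paed, paed_sim.population)
        band_15_19 = PAED_4.index_of("15-19")
        for row in t.panels[0].rows:
            assert row.total_0_19 == row.total_0_14 + row.counts.band_counts[band_15_19]

    def test_rates_are_per_million(self):
        records = [paed_rec(age=2, iccc="Ia")]
        pop_csv = "ageband,male,female\n" + "\n".join(f"{b.label},500000,500000" for b in PAED_4.bands)
        pop = parse_population_csv(pop_csv, PAED_4)
        t = build_paediatric_table(TableType.PAED_BOTH, records, pop)
        row = next(r for r in t.panels[0].rows if r.code == "Ia")
        assert row.rates_by_band[0] == pytest.approx(1.0)  # 1 case / 1e6 PY both sexes

    def test_non_malignant_behaviour_filtered_by_default(self):
        records = [paed_rec(iccc="Ia", behaviour=3), paed_rec(iccc="Ia", behaviour=1)]
        t = build_paediatric_table(TableType.PAED_BOTH, records)
        row = next(r for r in t.panels[0].rows if r.code == "Ia")
        assert row.total_0_19 == 1
        assert t.panels[0].excluded == 1
        t2 = build_paediatric_table(TableType.PAED_BOTH, records, include_behaviours=(1, 3))
        assert next(r for r in t2.panels[0].rows if r.code == "Ia").total_0_19 == 2

    def test_unclassified_codes_reported_in_output(self):
        records = [paed_rec(iccc="Q9")]
        t = build_paediatric_table(TableType.PAED_BOTH, records)
        panel = t.panels[0]
        assert panel.unclassified is not None
        assert panel.unclassified.total_0_19 == 1

    def test_mv_dco_percentages_from_basis_codes(self):
        records = [paed_rec(basis=7), paed_rec(basis=7), paed_rec(basis=1), paed_rec(basis=0)]
        t = build_paediatric_table(TableType.PAED_BOTH, records)
        row = next(r for r in t.panels[0].rows if r.code == "Ia")
        assert row.mv_percent == pytest.approx(50.0)
        assert row.dco_percent == pytest.approx(25.0)
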