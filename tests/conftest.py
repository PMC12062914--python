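from dataclasses import dataclass
from datetime import date

import numpy as np
import pytest

from registab.classification import ALL_AGES_16, PAED_4, load_basis_codes, load_iccc, load_site_groups
from registab.demography import PopulationDataset, parse_population_csv, world_standard
from registab.registry_io import ColumnMapping, filter_by_period, parse_registry_csv
from registab.simulate import SimulationSpec, StratumSpec, default_mapping_columns, simulate_registry


@pytest.fixture(scope="session")
def site_scheme():
    return load_site_groups()


@pytest.fixture(scope="session")
def iccc_scheme():
    return load_iccc()


@pytest.fixture(scope="session")
def basis_table():
    return load_basis_codes()


@pytest.fixture(scope="session")
def segi16():
    return world_standard(ALL_AGES_16)


@dataclass
class SimBundle:
    spec: SimulationSpec
    case_csv: str
    population_csv: str
    truth: dict
    records: list
    population: PopulationDataset
    period: tuple[date, date]


def _bundle(spec: SimulationSpec) -> SimBundle:
    sim = simulate_registry(spec)
    mapping = ColumnMapping(spec.family, default_mapping_columns(spec.family))
    records, report = parse_registry_csv(sim.case_csv, mapping)
    assert report.status == "pass"
    pop = parse_population_csv(sim.population_csv, spec.scheme)
    return SimBundle(
        spec,
        sim.case_csv,
        sim.population_csv,
        sim.truth,
        records,
        pop,
        (date(spec.years[0], 1, 1), date(spec.years[1], 12, 31)),
    )


@pytest.fixture(scope="session")
def allages_sim() -> SimBundle:
    """Two-site all-ages registry over 2018-2019 with known true rates."""
    py = np.full(16, 40_000.0)
    spec = SimulationSpec(
        "all_ages",
        ALL_AGES_16,
        (2018, 2019),
        (
            StratumSpec("C50", "female", np.linspace(5.0, 80.0, 16)),
            StratumSpec("C34", "male", np.full(16, 25.0)),
            StratumSpec("C16", "male", np.full(16, 12.0)),
        ),
        {"male": py, "female": py},
        case_fatality=0.4,
        death_delay_mean_days=200.0,
        seed=20180101,
    )
    return _bundle(spec)


@pytest.fixture(scope="session")
def paed_sim() -> SimBundle:
    """Paediatric registry with cases in every ICCC-3 main group and subgroup."""
    scheme = load_iccc()
    codes = []
    for main in scheme.main_groups:
        codes.append(main.code)
        codes.extend(s.code for s in main.subgroups)
    py = np.full(4, 150_000.0)
    strata = tuple(
        StratumSpec(code, sex, np.full(4, 10.0)) for code in codes for sex in ("male", "female")
    )
    spec = SimulationSpec(
        "paediatric",
        PAED_4,
        (2018, 2019),
        strata,
        {"male": py, "female": py},
        p_mv=0.8,
        p_dco=0.05,
        seed=20190101,
    )
    return _bundle(spec)


@pytest.fixture
def filtered_allages(allages_sim):
    return filter_by_period(allages_sim.records, "incidence", *allages_sim.period)


@pytest.fixture
def filtered_paed(paed_sim):
    return filter_by_period(paed_sim.records, "incidence", *paed_sim.period)
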