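"""Registry case-file parsing, validation and period filtering.

The input dialect is the one registry staff export from CanReg5 or a
spreadsheet: RFC-4180-style CSV with a header row, dates written as eight
digits YYYYMMDD, a sentinel date of death ``19000101`` and a sentinel age at
death ``99`` meaning "alive / unknown", and no blank cell permitted in any
mapped column.  Verification is all-or-nothing: a file with any rule
violation yields no records, only a row-level error report.

Two column families exist.  All-ages incidence/mortality tables need age,
sex, incidence date, histology, ICD-10 code, date of death and age at
death; paediatric ICCC-3 tables need age, sex, incidence date, basis of
diagnosis, behaviour, ICCC code, date of death and age at death.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, TextIO

__all__ = [
    "ALL_AGES_FIELDS",
    "PAEDIATRIC_FIELDS",
    "MALE",
    "FEMALE",
    "DEATH_DATE_SENTINEL",
    "AGE_AT_DEATH_SENTINEL",
    "ColumnMapping",
    "MappingError",
    "RegistryRecord",
    "RowError",
    "ValidationReport",
    "parse_registry_csv",
    "serialize_records",
    "filter_by_period",
]

ALL_AGES_FIELDS = ("age", "sex", "incidence_date", "histology", "icd10", "date_of_death", "age_at_death")
PAEDIATRIC_FIELDS = (
    "age",
    "sex",
    "incidence_date",
    "basis_of_diagnosis",
    "behaviour",
    "iccc_code",
    "date_of_death",
    "age_at_death",
)
_FIELDS_BY_FAMILY = {"all_ages": ALL_AGES_FIELDS, "paediatric": PAEDIATRIC_FIELDS}

MALE = 1
FEMALE = 2
DEFAULT_SEX_CODES = {"1": MALE, "2": FEMALE}

#: Raw token meaning "alive or date of death unknown"; compared before date
#: parsing so it never round-trips into a real 1900-01-01.
DEATH_DATE_SENTINEL = "19000101"
#: Raw token meaning "age at death unknown / alive".
AGE_AT_DEATH_SENTINEL = "99"


class MappingError(ValueError):
    """Column mapping does not fit the file or the table family."""


@dataclass(frozen=True)
class ColumnMapping:
    """Required field -> source column name, for one table family."""

    family: str  # "all_ages" | "paediatric"
    columns: dict[str, str]

    def __post_init__(self) -> None:
        if self.family not in _FIELDS_BY_FAMILY:
            raise MappingError(f"unknown table family {self.family!r}")
        required = _FIELDS_BY_FAMILY[self.family]
        missing = [f for f in required if f not in self.columns or not self.columns[f]]
        if missing:
            raise MappingError(f"unmapped required fields: {', '.join(missing)}")
        targets = [self.columns[f] for f in required]
        if len(set(targets)) != len(targets):
            raise MappingError("two required fields map to the same column")

    @property
    def fields(self) -> tuple[str, ...]:
        return _FIELDS_BY_FAMILY[self.family]

    def check_header(self, header: Iterable[str]) -> None:
        present = set(header)
        absent = [c for c in (self.columns[f] for f in self.fields) if c not in present]
        if absent:
            raise MappingError(f"mapped columns absent from file header: {', '.join(absent)}")


@dataclass(frozen=True)
class RegistryRecord:
    """One case/death row after column mapping and sentinel decoding.

    ``date_of_death`` / ``age_at_death`` are None when the sentinel was
    present (alive or unknown).  No ordering between incidence date and
    death date is enforced: registries legitimately hold DCO cases whose
    recorded dates conflict.
    """

    age: int
    sex: int
    incidence_date: date
    date_of_death: date | None
    age_at_death: int | None
    icd10: str | None = None
    histology: str | None = None
    basis_of_diagnosis: int | None = None
    behaviour: int | None = None
    iccc_code: str | None = None


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data-row number (header excluded)
    fieldname: str
    rule: str
    value: str


@dataclass
class ValidationReport:
    row_errors: list[RowError] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "pass" if not self.row_errors else "fail"

    def describe(self) -> str:
        if self.status == "pass":
            return "verification successful"
        lines = ["verification unsuccessful:"]
        lines += [
            f"  row {e.row}: field {e.fieldname!r} violates rule {e.rule!r} (value {e.value!r})"
            for e in self.row_errors
        ]
        return "\n".join(lines)


def _parse_yyyymmdd(token: str) -> date | None:
    if len(token) != 8 or not token.isdigit():
        return None
    try:
        return datetime.strptime(token, "%Y%m%d").date()
    except ValueError:
        return None


def parse_registry_csv(
    raw_csv: str | TextIO,
    mapping: ColumnMapping,
    sex_codes: dict[str, int] | None = None,
) -> tuple[list[RegistryRecord], ValidationReport]:
    """Parse and verify a registry case file.

    Returns ``(records, report)``; on any rule violation the verification
    fails closed — the record list is empty and every violation is reported
    with its row number.  UTF-8 BOMs are tolerated; the delimiter is a comma.
    """
    sex_codes = sex_codes or DEFAULT_SEX_CODES
    if isinstance(raw_csv, str):
        raw_csv = io.StringIO(raw_csv)
    reader = csv.DictReader(raw_csv)
    if reader.fieldnames is None:
        raise OSError("empty input: no header row")
    header = [h.lstrip("﻿") for h in reader.fieldnames]
    reader.fieldnames = header
    mapping.check_header(header)

    report = ValidationReport()
    records: list[RegistryRecord] = []

    for rowno, row in enumerate(reader, start=1):
        values: dict[str, str] = {}
        blank = False
        for fieldname in mapping.fields:
            cell = (row.get(mapping.columns[fieldname]) or "").strip()
            if not cell:
                report.row_errors.append(RowError(rowno, fieldname, "no blank data", ""))
                blank = True
            values[fieldname] = cell
        if blank:
            continue
        rec = _decode_row(rowno, values, mapping.family, sex_codes, report)
        if rec is not None:
            records.append(rec)

    if report.status == "fail":
        return [], report
    return records, report


def _decode_row(
    rowno: int,
    v: dict[str, str],
    family: str,
    sex_codes: dict[str, int],
    report: ValidationReport,
) -> RegistryRecord | None:
    errors_before = len(report.row_errors)

    def fail(fieldname: str, rule: str) -> None:
        report.row_errors.append(RowError(rowno, fieldname, rule, v[fieldname]))

    age = _parse_nonneg_int(v["age"])
    if age is None:
        fail("age", "age must be a non-negative integer")

    sex = sex_codes.get(v["sex"])
    if sex is None:
        fail("sex", "sex code")

    incidence_date = _parse_yyyymmdd(v["incidence_date"])
    if incidence_date is None:
        fail("incidence_date", "date format")

    # Sentinels are matched on the raw token, before any date parsing.
    if v["date_of_death"] == DEATH_DATE_SENTINEL:
        date_of_death: date | None = None
    else:
        date_of_death = _parse_yyyymmdd(v["date_of_death"])
        if date_of_death is None:
            fail("date_of_death", "date format")

    if v["age_at_death"] == AGE_AT_DEATH_SENTINEL:
        age_at_death: int | None = None
    else:
        age_at_death = _parse_nonneg_int(v["age_at_death"])
        if age_at_death is None:
            fail("age_at_death", "age at death must be a non-negative integer or 99")

    extra: dict[str, object] = {}
    if family == "all_ages":
        extra["icd10"] = v["icd10"]
        extra["histology"] = v["histology"]
    else:
        basis = _parse_nonneg_int(v["basis_of_diagnosis"])
        if basis is None or basis > 9:
            fail("basis_of_diagnosis", "basis of diagnosis must be a single digit 0-9")
        behaviour = _parse_nonneg_int(v["behaviour"])
        if behaviour is None or behaviour > 9:
            fail("behaviour", "behaviour must be a single digit 0-9")
        extra.update(basis_of_diagnosis=basis, behaviour=behaviour, iccc_code=v["iccc_code"])

    if len(report.row_errors) > errors_before:
        return None
    return RegistryRecord(
        age=age,  # type: ignore[arg-type]
        sex=sex,  # type: ignore[arg-type]
        incidence_date=incidence_date,  # type: ignore[arg-type]
        date_of_death=date_of_death,
        age_at_death=age_at_death,
        **extra,  # type: ignore[arg-type]
    )


def _parse_nonneg_int(token: str) -> int | None:
    if not token.isdigit():
        return None
    return int(token)


def serialize_records(records: Iterable[RegistryRecord], mapping: ColumnMapping) -> str:
    """Write records back to the input dialect (sentinels re-encoded).

    Round-trips: parsing the result under the same mapping reproduces the
    records exactly.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([mapping.columns[f] for f in mapping.fields])
    inverse_sex = {MALE: "1", FEMALE: "2"}
    for r in records:
        cells = []
        for f in mapping.fields:
            if f == "age":
                cells.append(str(r.age))
            elif f == "sex":
                cells.append(inverse_sex[r.sex])
            elif f == "incidence_date":
                cells.append(r.incidence_date.strftime("%Y%m%d"))
            elif f == "date_of_death":
                cells.append(DEATH_DATE_SENTINEL if r.date_of_death is None else r.date_of_death.strftime("%Y%m%d"))
            elif f == "age_at_death":
                cells.append(AGE_AT_DEATH_SENTINEL if r.age_at_death is None else str(r.age_at_death))
            else:
                cells.append(str(getattr(r, f)))
        writer.writerow(cells)
    return buf.getvalue()


def filter_by_period(
    records: list[RegistryRecord],
    table_type,
    date_from: date,
    date_to: date,
) -> list[RegistryRecord]:
    """Keep the records whose governing date falls in the inclusive period.

    Incidence-family tables (including all paediatric tables) filter on the
    incidence date; mortality tables filter on the date of death, so records
    with an unknown death date can never enter a mortality table.
    ``table_type`` may be a :class:`registab.tables.TableType` or one of the
    strings ``"incidence"`` / ``"mortality"``.
    """
    if date_from > date_to:
        raise ValueError("date_from must not be after date_to")
    basis = getattr(table_type, "basis", table_type)
    if basis not in ("incidence", "mortality"):
        raise ValueError(f"unknown table basis {basis!r}")
    if basis == "incidence":
        return [r for r in records if date_from <= r.incidence_date <= date_to]
    return [r for r in records if r.date_of_death is not None and date_from <= r.date_of_death <= date_to]
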