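"""Classification schemes used by registry tables.

Three kinds of scheme are shipped as editable data files under
``registab/data`` so that registries can substitute national variants
without touching code:

* age-band schemes (the all-ages 5-year banding 0--4 ... 75+, and the two
  paediatric bandings 0--19, one with a separate single-year age-0 band);
* the 53-entry ICD-10 site grouping used for all-ages incidence and
  mortality tables (a partition of C00--C97 at 3-character category level);
* the ICCC-3 childhood-cancer structure (12 main groups, 47 subgroups) and
  the IARC/IACR basis-of-diagnosis code roles that define microscopic
  verification (MV) and death-certificate-only (DCO) status.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources

logger = logging.getLogger("registab")

__all__ = [
    "AgeBand",
    "AgeBandScheme",
    "ALL_AGES_16",
    "PAED_4",
    "PAED_5_ZERO",
    "SiteGroup",
    "SiteGroupScheme",
    "ICCCSubgroup",
    "ICCCMainGroup",
    "ICCCScheme",
    "BasisCodeTable",
    "load_site_groups",
    "load_iccc",
    "load_basis_codes",
    "is_microscopically_verified",
    "is_dco",
]


# ---------------------------------------------------------------------------
# Age bands


@dataclass(frozen=True)
class AgeBand:
    """One age band, inclusive at both ends; ``upper=None`` means open-ended."""

    label: str
    lower: int
    upper: int | None

    @property
    def width(self) -> int | None:
        """Band width in years (None for the open-ended band)."""
        return None if self.upper is None else self.upper - self.lower + 1

    def contains(self, age: int) -> bool:
        if age < self.lower:
            return False
        return self.upper is None or age <= self.upper


@dataclass(frozen=True)
class AgeBandScheme:
    """An ordered, disjoint, contiguous-from-zero set of age bands."""

    name: str
    bands: tuple[AgeBand, ...]

    def __post_init__(self) -> None:
        expect = 0
        for b in self.bands:
            if b.lower != expect:
                raise ValueError(f"bands of {self.name!r} not contiguous at {b.label!r}")
            if b.upper is not None and b.upper < b.lower:
                raise ValueError(f"band {b.label!r} has upper < lower")
            expect = -1 if b.upper is None else b.upper + 1
        if any(b.upper is None for b in self.bands[:-1]):
            raise ValueError("only the last band may be open-ended")

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.bands)

    def assign(self, age: int | None) -> int | None:
        """Band index containing ``age``; None for unknown or out-of-scheme ages."""
        if age is None or age < 0:
            return None
        for i, b in enumerate(self.bands):
            if b.contains(age):
                return i
        return None

    def index_of(self, label: str) -> int:
        norm = label.strip().lower()
        for i, b in enumerate(self.bands):
            if b.label.lower() == norm:
                return i
        raise KeyError(label)

    def indices_within(self, lower: int, upper: int) -> list[int]:
        """Indices of bands wholly inside the inclusive age span [lower, upper]."""
        return [
            i
            for i, b in enumerate(self.bands)
            if b.lower >= lower and b.upper is not None and b.upper <= upper
        ]


def _five_year(lo: int, hi: int) -> AgeBand:
    return AgeBand(f"{lo}-{hi}", lo, hi)


#: 16-band all-ages scheme: 0-4, 5-9, ..., 70-74, 75+.
ALL_AGES_16 = AgeBandScheme(
    "ALL_AGES_16",
    tuple(_five_year(5 * i, 5 * i + 4) for i in range(15)) + (AgeBand("75+", 75, None),),
)

#: Paediatric scheme 0-19 in 5-year bands.
PAED_4 = AgeBandScheme("PAED_4", tuple(_five_year(5 * i, 5 * i + 4) for i in range(4)))

#: Paediatric scheme with a separate single-year age-0 band.
PAED_5_ZERO = AgeBandScheme(
    "PAED_5_ZERO",
    (AgeBand("0", 0, 0), AgeBand("1-4", 1, 4), _five_year(5, 9), _five_year(10, 14), _five_year(15, 19)),
)

SCHEMES_BY_NAME = {s.name: s for s in (ALL_AGES_16, PAED_4, PAED_5_ZERO)}


# ---------------------------------------------------------------------------
# ICD-10 site grouping


_CATEGORY_RE = re.compile(r"^C\d{2}$")


def _expand_codes(spec: str) -> frozenset[str]:
    """Expand 'C01-C02;C96' into the set of 3-character categories."""
    out: set[str] = set()
    for part in spec.split(";"):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-")
            for n in range(int(lo[1:]), int(hi[1:]) + 1):
                out.add(f"C{n:02d}")
        elif part:
            out.add(part)
    for code in out:
        if not _CATEGORY_RE.match(code):
            raise ValueError(f"bad ICD-10 category {code!r} in {spec!r}")
    return frozenset(out)


@dataclass(frozen=True)
class SiteGroup:
    label: str
    codes: frozenset[str]
    residual: bool = False
    codes_spec: str = ""  # display form, e.g. "C33-C34"


@dataclass(frozen=True)
class SiteGroupScheme:
    """Ordered site entries partitioning ICD-10 C00--C97.

    Exactly one entry is the residual ("Other and unspecified") entry: it
    owns its listed codes plus every C00--C97 category no other entry claims.
    """

    entries: tuple[SiteGroup, ...]
    _index: dict[str, int] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        residuals = [i for i, e in enumerate(self.entries) if e.residual]
        if len(residuals) != 1:
            raise ValueError("scheme must have exactly one residual entry")
        seen: dict[str, int] = {}
        for i, e in enumerate(self.entries):
            for code in e.codes:
                if code in seen:
                    raise ValueError(f"{code} claimed by two entries")
                seen[code] = i
        residual = residuals[0]
        for n in range(98):  # every category C00..C97 resolves somewhere
            seen.setdefault(f"C{n:02d}", residual)
        object.__setattr__(self, "_index", seen)

    def __len__(self) -> int:
        return len(self.entries)

    def assign(self, icd10_code: str) -> int | None:
        """Entry index for an ICD-10 token, or None for non-neoplasm codes.

        The token is truncated to its 3-character category ("C50.9" -> "C50");
        site groups are defined at category level.
        """
        token = icd10_code.strip().upper()
        if not token:
            raise ValueError("empty ICD-10 code")
        category = token.replace(".", "")[:3]
        idx = self._index.get(category)
        if idx is None:
            logger.warning("ICD-10 code %r outside C00-C97; excluded from site rows", icd10_code)
        return idx


def load_site_groups() -> SiteGroupScheme:
    """Load the shipped 53-site grouping."""
    entries = []
    for row in _read_data_csv("site_groups.csv"):
        entries.append(
            SiteGroup(
                row["label"],
                _expand_codes(row["codes"]),
                residual=row["residual"] == "1",
                codes_spec=row["codes"].replace(";", ", "),
            )
        )
    return SiteGroupScheme(tuple(entries))


# ---------------------------------------------------------------------------
# ICCC-3


@dataclass(frozen=True)
class ICCCSubgroup:
    code: str
    label: str


@dataclass(frozen=True)
class ICCCMainGroup:
    code: str
    label: str
    subgroups: tuple[ICCCSubgroup, ...]


_ICCC_TOKEN_RE = re.compile(r"^([ivxIVX]+)\s*([a-fA-F]?)$")


def normalize_iccc_token(token: str) -> str:
    """Canonical ICCC key: upper-case Roman numeral + lower-case letter."""
    m = _ICCC_TOKEN_RE.match(token.strip())
    if not m:
        return token.strip()
    return m.group(1).upper() + m.group(2).lower()


@dataclass(frozen=True)
class ICCCScheme:
    """The ICCC-3 hierarchy: 12 main groups, 47 subgroups."""

    main_groups: tuple[ICCCMainGroup, ...]

    def lookup(self, iccc_code: str) -> tuple[int, int | None] | None:
        """Resolve a token to (main index, subgroup index within main) or None.

        Subgroup keys are tried first ("Ia" -> (0, 0)); a bare main-group key
        resolves to (main, None); anything else is unclassified.
        """
        key = normalize_iccc_token(iccc_code)
        for i, main in enumerate(self.main_groups):
            for j, sub in enumerate(main.subgroups):
                if sub.code == key:
                    return (i, j)
        for i, main in enumerate(self.main_groups):
            if main.code == key:
                return (i, None)
        return None

    @property
    def n_subgroups(self) -> int:
        return sum(len(m.subgroups) for m in self.main_groups)


def load_iccc() -> ICCCScheme:
    """Load the shipped ICCC-3 structure."""
    mains: list[tuple[str, str, list[ICCCSubgroup]]] = []
    by_code: dict[str, list[ICCCSubgroup]] = {}
    for row in _read_data_csv("iccc3.csv"):
        code, label, parent = row["code"], row["label"], row["parent"]
        if parent:
            if parent not in by_code:
                raise ValueError(f"subgroup {code} precedes its main group {parent}")
            by_code[parent].append(ICCCSubgroup(code, label))
        else:
            subs: list[ICCCSubgroup] = []
            mains.append((code, label, subs))
            by_code[code] = subs
    return ICCCScheme(tuple(ICCCMainGroup(c, l, tuple(s)) for c, l, s in mains))


# ---------------------------------------------------------------------------
# Basis of diagnosis


@dataclass(frozen=True)
class BasisCodeTable:
    """Maps basis-of-diagnosis codes to their data-quality role."""

    roles: dict[int, str]

    def _role(self, basis_code: int) -> str:
        if basis_code not in self.roles:
            raise ValueError(f"basis-of-diagnosis code {basis_code!r} out of range")
        return self.roles[basis_code]

    def is_microscopically_verified(self, basis_code: int) -> bool:
        return self._role(basis_code) == "microscopic"

    def is_dco(self, basis_code: int) -> bool:
        return self._role(basis_code) == "dco"


def load_basis_codes() -> BasisCodeTable:
    return BasisCodeTable({int(r["code"]): r["role"] for r in _read_data_csv("basis_of_diagnosis.csv")})


_DEFAULT_BASIS: BasisCodeTable | None = None


def _default_basis() -> BasisCodeTable:
    global _DEFAULT_BASIS
    if _DEFAULT_BASIS is None:
        _DEFAULT_BASIS = load_basis_codes()
    return _DEFAULT_BASIS


def is_microscopically_verified(basis_code: int, table: BasisCodeTable | None = None) -> bool:
    """True iff the basis code denotes a microscopically verified case (MV)."""
    return (table or _default_basis()).is_microscopically_verified(basis_code)


def is_dco(basis_code: int, table: BasisCodeTable | None = None) -> bool:
    """True iff the case is known through a death certificate only (DCO)."""
    return (table or _default_basis()).is_dco(basis_code)


# ---------------------------------------------------------------------------


def _read_data_csv(name: str) -> list[dict[str, str]]:
    text = resources.files("registab.data").joinpath(name).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    return list(csv.DictReader(lines))
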