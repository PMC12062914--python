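# Methods

## Input dialect and verification

Case files are RFC-4180-style CSV with a header row; the user supplies a
column mapping (required field → column header) for one of two families:
all-ages tables (age, sex, incidence date, histology, ICD-10, date of death,
age at death) or paediatric tables (age, sex, incidence date, basis of
diagnosis, behaviour, ICCC code, date of death, age at death). Dates are
eight digits `YYYYMMDD`. Two sentinels mark "alive / unknown": date of death
`19000101` and age at death `99`. Sentinels are compared on the raw token
*before* date parsing, so the death sentinel never round-trips into a real
1900-01-01; the consequence is that a genuine death on 1900-01-01 (or a
genuine age at death of 99) cannot be represented — an accepted limitation
of the dialect itself.

Verification is fail-closed and all-or-nothing: any blank mapped cell,
malformed date, bad sex/basis/behaviour code or negative age anywhere in the
file yields an empty record list and a complete row-level error report.
Rationale: a registry report built from a silently half-parsed file is worse
than no report. Duplicate rows are **not** deduplicated (that is upstream
registry QC), no incidence-date/age consistency check is applied, and no
ordering between incidence date and death date is enforced (DCO cases
legitimately violate it). Sex codes default to 1 = male, 2 = female
(CanReg5 export convention) and are configurable.

## Period filtering

The report period is inclusive at both ends; year-only endpoints on the CLI
expand to January 1 / December 31. Incidence-family tables (including all
paediatric tables) filter on the incidence date; mortality tables filter on
the date of death, so sentinel (alive/unknown) records can never enter a
mortality table. For multi-year periods the population file must already
contain the person-years summed over the period; `sum_periods` combines
single-year files, and no interpolation or projection is performed.

## Classification

*Age bands.* Three schemes: 0–4 … 75+ (16 bands, all-ages), 0–4 … 15–19
(paediatric), and the paediatric variant with a separate single-year age-0
band. Band assignment is a total function; unknown or out-of-scheme ages go
to an "unassigned" column.

*Sites.* The all-ages tables use a 53-entry ICD-10 grouping shipped as an
editable data file (`registab/data/site_groups.csv`) following the
CI5/Indian-registry report convention, from Lip (C00) through Leukaemia
(C91–C95) to an "Other and unspecified" residual entry. Matching is at the
3-character category level (C50.9 → C50); the residual entry additionally
absorbs any C00–C97 category no other entry claims, so the 53 entries
partition C00–C97 exactly. Codes outside C00–C97 are excluded from the site
rows (and from the All-sites aggregate) and counted in the run log. The
exact site inventory is a convention, not a computation: registries with a
national variant can substitute the data file.

*ICCC-3.* The paediatric scheme ships the published ICCC-3 structure: 12
main groups (Roman numerals I–XII) and 47 subgroups. Group V
(retinoblastoma) carries no subgroups — that is how the published structure
reaches 47 rather than 48. Lookup tries subgroup keys first, then main
groups; tokens are case-normalized ("ia" → "Ia"); unknown tokens are
reported in an explicit UNCLASSIFIED row rather than dropped. A main-group
row counts its subgroup-coded cases plus cases coded only to the main group,
so main ≥ sum(subgroups) holds on real data. No ICD-O-3 → ICCC-3 auto-coding
is attempted; the input carries the ICCC code.

*Basis of diagnosis.* IARC/IACR convention, shipped as data: code 0 is DCO,
codes 5–8 (cytology/haematology, histology of metastasis, histology of
primary, autopsy with histology) are microscopic; MV and DCO are mutually
exclusive by construction. Paediatric tables default to tabulating
behaviour code 3 (malignant) only, switchable via `include_behaviours` to
include non-malignant CNS tumours where a registry follows that practice.

## Rate statistics

All statistics are computed at full double precision and rounded only at
export (rates and percentages to 1 decimal, cumulative rates/risks to 2).
With counts *n·i*, person-years *PY·i* and standard weights *w·i* per band:

- age-specific rate: *n·i / PY·i × scale* (scale 100,000 all-ages,
  1,000,000 paediatric). A band with zero person-years has no defined rate:
  it is rendered missing, excluded from weighted statistics, and logged if
  it holds cases.
- crude rate: *Σn·i / ΣPY·i × scale*; unknown-age cases count in the
  numerator (and in the total-cases column) but in no age-structured
  statistic — standard registry practice.
- ASR: *Σw·i r·i / Σw·i* (invariant to rescaling the standard). The shipped
  standard is the Segi (1960) world standard used by CI5 (sums to 100,000);
  it is data, so a registry preferring the WHO 2000 standard can swap it.
  The truncated rate restricts to ages 35–64 (registry convention;
  configurable span).
- cumulative rate to age L ∈ {64, 74}: *100 Σ width·i × r·i / scale* over
  the bands wholly below L+1; the open 75+ band never contributes.
  Cumulative risk: *100 (1 − exp(−cum/100))*, the probability of developing
  the cancer before age L+1 absent competing mortality; person risk is
  *round(100 / risk%)*, floored at 1, and undefined (rendered "-") at zero
  risk.
- paediatric AAR: the same weighted mean over the 0–14 segment and the full
  0–19 span, with Segi segment weights; for the separate-zero scheme the
  Segi 0–4 weight is split 1:4 between age 0 and ages 1–4 (uniform
  single-year assumption), documented here and overridable by supplying a
  custom standard.
- MV% and DCO% are per-stratum percentages of total cases; the M:I ratio is
  mortality count over incidence count, undefined at zero incidence.

All-ages mortality tables band by **age at death** (the field the input
requires) rather than age at incidence; records with a known death date but
unknown age at death fall in the unassigned column.

## Synthetic registry generator

The generator exists so that every stage — dialect parsing, filtering,
classification, tabulation, export — is testable end-to-end with known
truth. Per stratum (site/ICCC code × sex), band counts are Poisson with
mean *rate × PY / 100,000*; ages are uniform within band (75+ spans 15
years), incidence dates uniform over the period; a case dies with the
case-fatality probability (default 0.3) after an exponential delay (default
mean 365 days), censored at period end — censored cases get the alive
sentinels. Paediatric basis codes are drawn so the marginal MV and DCO
probabilities equal `p_mv` (default 0.85) and `p_dco` (default 0.03),
values typical of a registry with good diagnostic verification. Defaults
for the fixtures: two-year period, tens of thousands of person-years per
band, rates of order 10–80 per 100,000 — small enough to run in
milliseconds, large enough that Poisson noise is a few percent.

`expected_tables` recomputes every expected statistic by direct summation
with explicit loops, independent of the rate engine, and the test suite
also carries a second pure-Python oracle; recovery tests assert agreement
within 3 Poisson / binomial standard errors on seeded draws, and the
formula oracle asserts 1e-10 relative agreement on 1,000 random instances.

What the generator does **not** emulate: real age–incidence curves,
within-band age structure, secular trends, duplicate registrations, coding
errors, or the correlation between site and survival. Passing tests
therefore demonstrate the *arithmetic and plumbing* are right under the
stated sampling model, not that any epidemiological pattern is realistic.

## Exports and determinism

CSV is the normative export: fixed column layout per table type, LF line
endings, missing statistics as "-"; identical inputs give byte-identical
files (row order is fixed by the scheme data files). Outputs are written to
a temporary file and renamed, so a failed run leaves nothing behind. The
PDF export is a deliberately minimal tabular rendering of the same cells —
presentation, not a second computation path.

## Known limitations

- No confidence intervals or standard errors for rates.
- No survival statistics.
- A single ICD-10 column serves both incidence and mortality tables; a
  registry coding cause of death separately must map that column when
  requesting mortality tables.
- The 53-site inventory and the choice of the Segi standard are
  conventions shipped as data, not outputs of the engine.
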