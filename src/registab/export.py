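"""Table serialization.

CSV is the normative export: a fixed, byte-stable layout per table type
(identical inputs always produce identical bytes, so registry reports are
diffable across runs).  Rounding follows registry-report style — rates and
percentages to one decimal, cumulative risks to two; a statistic with no
defined value ("one in N" at zero risk, MV% of an empty row) renders as
"-".  PDF is a secondary, minimal tabular rendering of the same cells.
"""

from __future__ import annotations

import csv
import math
import os

from .tables import AllAgesTable, PaediatricTable, PaediatricTableRow

__all__ = ["write_table_csv", "write_table_pdf", "table_cells"]


def _fmt(x, decimals: int = 1) -> str:
    if x is None:
        return "-"
    if isinstance(x, float) and math.isnan(x):
        return "-"
    if isinstance(x, (int,)) and not isinstance(x, bool):
        return str(x)
    return f"{x:.{decimals}f}"


def _all_ages_cells(table: AllAgesTable) -> tuple[list[str], list[list[str]]]:
    bands = list(table.band_scheme.labels)
    if table.table_type.rates:
        header = (
            ["Site", "ICD-10", "Cases"]
            + bands
            + [
                "Crude",
                "TR 35-64",
                "Cum rate 0-64",
                "Cum rate 0-74",
                "Cum risk 0-64",
                "Cum risk 0-74",
                "One in N 0-64",
                "One in N 0-74",
                "ASR",
            ]
        )
    else:
        header = ["Site", "ICD-10"] + bands + ["Unknown age", "Total"]
    rows = []
    for row in table.rows + [table.all_sites]:
        cells = [row.label, row.codes]
        if table.table_type.rates:
            s = row.stats
            cells.append(str(row.counts.total))
            cells += [_fmt(float(r)) for r in s.age_specific]
            cells += [
                _fmt(s.crude),
                _fmt(s.truncated),
                _fmt(s.cumulative_rate_0_64, 2),
                _fmt(s.cumulative_rate_0_74, 2),
                _fmt(s.cumulative_risk_0_64, 2),
                _fmt(s.cumulative_risk_0_74, 2),
                _fmt(s.person_risk_64),
                _fmt(s.person_risk_74),
                _fmt(s.asr),
            ]
        else:
            cells += [str(int(c)) for c in row.counts.band_counts]
            cells += [str(row.counts.unassigned), str(row.counts.total)]
        rows.append(cells)
    return header, rows


def _paediatric_cells(table: PaediatricTable) -> tuple[list[str], list[list[str]]]:
    bands = list(table.band_scheme.labels)
    header = (
        ["ICCC", "Diagnostic group"]
        + bands
        + ["0-14", "0-19"]
        + [f"% {b}" for b in bands]
        + [f"Rate {b}" for b in bands]
        + ["AAR 0-14", "AAR 0-19", "MV %", "DCO %"]
    )
    rows: list[list[str]] = []
    multi_panel = len(table.panels) > 1
    for panel in table.panels:
        if multi_panel:
            rows.append([panel.sex.upper()] + [""] * (len(header) - 1))
        panel_rows = panel.rows + ([panel.unclassified] if panel.unclassified else [])
        for row in panel_rows:
            rows.append(_paed_row_cells(row))
    return header, rows


def _paed_row_cells(row: PaediatricTableRow) -> list[str]:
    # subgroup rows are indented via a label prefix in the first column
    code = ("  " + row.code) if row.is_subgroup else row.code
    cells = [code, row.label]
    cells += [str(int(c)) for c in row.counts.band_counts]
    cells += [str(row.total_0_14), str(row.total_0_19)]
    cells += [_fmt(float(p)) for p in row.percent_by_band]
    n_bands = len(row.counts.band_counts)
    if row.rates_by_band is None:
        cells += ["-"] * n_bands + ["-", "-"]
    else:
        cells += [_fmt(float(r)) for r in row.rates_by_band]
        cells += [_fmt(row.aar_0_14), _fmt(row.aar_0_19)]
    cells += [_fmt(row.mv_percent), _fmt(row.dco_percent)]
    return cells


def table_cells(table: AllAgesTable | PaediatricTable) -> tuple[list[str], list[list[str]]]:
    """(header, rows) of formatted cells, shared by the CSV and PDF writers."""
    if isinstance(table, AllAgesTable):
        return _all_ages_cells(table)
    return _paediatric_cells(table)


def write_table_csv(table: AllAgesTable | PaediatricTable, destination: str | os.PathLike) -> None:
    """Write the table as CSV (LF line endings, UTF-8, byte-stable)."""
    header, rows = table_cells(table)
    with open(destination, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_table_pdf(table: AllAgesTable | PaediatricTable, destination: str | os.PathLike) -> None:
    """Render the same cells as a single-page PDF table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    header, rows = table_cells(table)
    n_rows, n_cols = len(rows) + 1, len(header)
    fig, ax = plt.subplots(figsize=(max(8.0, 0.55 * n_cols), max(4.0, 0.16 * n_rows)))
    ax.axis("off")
    tab = ax.table(cellText=rows, colLabels=header, loc="center", cellLoc="right")
    tab.auto_set_font_size(False)
    tab.set_fontsize(5)
    fig.savefig(destination, format="pdf", bbox_inches="tight")
    plt.close(fig)
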