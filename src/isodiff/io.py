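"""Readers and writers for the tab-delimited interchange formats.

Measurement tables are TSV with a header row: first column = feature id,
remaining columns = sample ids. Isotopologue tables are accepted in two
dialects:

* *flat* — feature ids follow the ``metabolite_m+i`` convention;
* *long* — two explicit leading columns ``metabolite`` and
  ``isotopologue_index``.

All writers emit UTF-8, Unix newlines, period decimal separator, and a
fixed ``%.12g`` float format so that identical runs produce bit-identical
files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .tables import (
    FRACTIONAL_CONTRIBUTION,
    TOTAL_ABUNDANCE,
    IsotopologueTable,
    MetaboliteTable,
    SampleSheet,
    StructuralError,
)

FLOAT_FORMAT = "%.12g"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={0: str})


def read_isotopologue_table(path: str | Path, mode: str) -> IsotopologueTable:
    """Read an isotopologue table, auto-detecting the dialect."""
    frame = _read_tsv(path)
    cols = [c.lower() for c in frame.columns[:2]]
    if cols == ["metabolite", "isotopologue_index"]:
        frame = frame.rename(
            columns={frame.columns[0]: "metabolite", frame.columns[1]: "isotopologue_index"}
        )
        frame["isotopologue_index"] = frame["isotopologue_index"].astype(int)
        frame = frame.set_index(["metabolite", "isotopologue_index"])
        if frame.index.duplicated().any():
            raise StructuralError(f"duplicated (metabolite, isotopologue) rows in {path}")
        return IsotopologueTable(data=frame.sort_index(), mode=mode)
    frame = frame.set_index(frame.columns[0])
    return IsotopologueTable.from_flat(frame, mode=mode)


def write_isotopologue_table(table: IsotopologueTable, path: str | Path) -> None:
    table.to_flat().to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n", encoding="utf-8"
    )


def read_metabolite_table(path: str | Path, quantity: str) -> MetaboliteTable:
    frame = _read_tsv(path)
    frame = frame.set_index(frame.columns[0])
    frame.index.name = "metabolite"
    return MetaboliteTable(data=frame, quantity=quantity)


def write_metabolite_table(table: MetaboliteTable, path: str | Path) -> None:
    table.data.to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n", encoding="utf-8"
    )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = _read_tsv(path)
    frame = frame.set_index(frame.columns[0])
    frame.index.name = "sample_id"
    return SampleSheet(data=frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def write_result_table(results: pd.DataFrame, path: str | Path) -> None:
    """Comparison results: stable row order, fixed float format."""
    results.to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, index=False,
        lineterminator="\n", encoding="utf-8",
    )


QUANTITY_FILES = {
    "isotopologue_absolute": "isotopologues_absolute.tsv",
    "isotopologue_proportion": "isotopologues_proportions.tsv",
    TOTAL_ABUNDANCE: "total_abundances.tsv",
    FRACTIONAL_CONTRIBUTION: "fractional_contributions.tsv",
    "samplesheet": "samplesheet.tsv",
}
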