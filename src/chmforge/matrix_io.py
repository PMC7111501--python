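"""Readers and writers for uploaded matrices.

Three dialects are accepted — tab-delimited text (``.txt``),
comma-separated text with RFC-4180 quoting (``.csv``) and Office Open
XML spreadsheets (``.xlsx``, first worksheet only, formula cells read as
their cached value).  All three parse to the same :class:`LabeledMatrix`
for the same logical table.

The writer emits tab-delimited UTF-8 with an ``NA`` missing sentinel;
``parse_matrix(write_matrix(m))`` is the identity.
"""

from __future__ import annotations

import csv
import os

import numpy as np

from chmforge.errors import FormatError, ValidationError
from chmforge.matrix import LabeledMatrix, RegionSpec, _check_axis, parse_cell


def read_raw_grid(path: str) -> list[list[object]]:
    """Read a file into a rectangular grid of raw cells (strings or
    spreadsheet values), without interpreting labels or data."""
    if not os.path.exists(path):
        raise IOError(f"cannot read {path!r}: file does not exist")
    ext = os.path.splitext(path)[1].lower()
    if ext == ".csv":
        with open(path, newline="", encoding="utf-8-sig") as fh:
            rows = [list(r) for r in csv.reader(fh)]
    elif ext in (".txt", ".tsv"):
        with open(path, newline="", encoding="utf-8-sig") as fh:
            rows = [list(r) for r in csv.reader(fh, delimiter="\t")]
    elif ext == ".xlsx":
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        ws = wb.worksheets[0]
        rows = [list(r) for r in ws.iter_rows(values_only=True)]
        wb.close()
    else:
        raise FormatError(
            f"unsupported matrix format {ext!r}; expected .txt, .csv or .xlsx"
        )
    width = max((len(r) for r in rows), default=0)
    for r in rows:
        r.extend([None] * (width - len(r)))
    return rows


def grid_to_matrix(grid: list[list[object]], region: RegionSpec) -> LabeledMatrix:
    """Carve a raw grid into labels and data according to ``region``."""
    r0, c0 = region.data_origin
    col_labels = [
        "" if v is None else str(v).strip()
        for v in (grid[region.label_row_index][c0:] if grid else [])
    ]
    row_labels = [
        "" if row[region.label_col_index] is None else str(row[region.label_col_index]).strip()
        for row in grid[r0:]
    ]
    n_rows, n_cols = len(row_labels), len(col_labels)
    if n_cols == 0 and n_rows > 0:
        raise ValidationError("empty data region: no data columns found")
    values = np.full((n_rows, n_cols), np.nan)
    n_invalid = 0
    for i, row in enumerate(grid[r0:]):
        for j, tok in enumerate(row[c0:]):
            v, bad = parse_cell(tok)
            values[i, j] = v
            n_invalid += bad
    return LabeledMatrix(row_labels, col_labels, values, n_invalid=n_invalid)


def parse_matrix(path: str, region: RegionSpec | None = None) -> LabeledMatrix:
    """Parse a matrix file into a :class:`LabeledMatrix`.

    Parameters
    ----------
    path:
        ``.txt`` (tab-delimited), ``.csv`` or ``.xlsx`` file.
    region:
        Optional :class:`RegionSpec` locating labels and data; when
        absent, row 0 holds column labels and column 0 holds row labels.
    """
    grid = read_raw_grid(path)
    if not grid:
        raise ValidationError(f"{path!r} is empty")
    return grid_to_matrix(grid, region or RegionSpec())


def dedupe_labels(m: LabeledMatrix, axis: str, mode: str = "rename") -> LabeledMatrix:
    """Disambiguate duplicate labels on one axis.

    The first occurrence keeps its name; occurrence *k* (2-based) becomes
    ``<label>_<k>``, escalating the suffix until unique.  Idempotent on
    already-unique labels.
    """
    _check_axis(axis)
    if mode != "rename":
        raise ValidationError(f"unknown dedupe mode {mode!r}")
    labels = m.labels(axis)
    seen: dict[str, int] = {}
    taken = set(labels)
    out: list[str] = []
    for lab in labels:
        count = seen.get(lab, 0) + 1
        seen[lab] = count
        if count == 1:
            out.append(lab)
            continue
        k = count
        new = f"{lab}_{k}"
        while new in taken or new in out:
            k += 1
            new = f"{lab}_{k}"
        out.append(new)
    result = m.copy()
    if axis == "row":
        result.row_labels = out
    else:
        result.col_labels = out
    return result


def format_number(v: float) -> str:
    """Render a float so that parsing it back reproduces it exactly."""
    if np.isnan(v):
        return "NA"
    return repr(float(v))


def write_matrix(m: LabeledMatrix, path: str, corner: str = "") -> None:
    """Write a matrix as tab-delimited UTF-8 text.

    Column labels form the header row (first cell is ``corner``), row
    labels fill the first column, missing cells are written as ``NA``.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join([corner] + list(m.col_labels)) + "\n")
        for i, lab in enumerate(m.row_labels):
            cells = [format_number(v) for v in m.values[i]]
            fh.write("\t".join([lab] + cells) + "\n")


def matrix_to_text(m: LabeledMatrix, corner: str = "") -> str:
    """The tab-delimited serialization of ``m`` as a string."""
    lines = ["\t".join([corner] + list(m.col_labels))]
    for i, lab in enumerate(m.row_labels):
        lines.append("\t".join([lab] + [format_number(v) for v in m.values[i]]))
    return "\n".join(lines) + "\n"


def matrix_from_text(text: str) -> LabeledMatrix:
    """Inverse of :func:`matrix_to_text`."""
    rows = [line.split("\t") for line in text.splitlines()]
    if not rows:
        raise ValidationError("empty matrix text")
    return grid_to_matrix(rows, RegionSpec())
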