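"""Covariate (classification) bars for either axis.

A covariate maps axis labels to categories (discrete) or numbers
(continuous).  Files are two-column text — label then value, tab- or
comma-delimited, one entry per line — the shape clinical annotation
tables are usually exported in.
"""

from __future__ import annotations

import csv
import json
import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from chmforge.errors import ValidationError
from chmforge.matrix import _check_axis

_HEX_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")

#: Okabe–Ito colorblind-safe palette, the seeded default of every store.
DEFAULT_PALETTE_COLORS = [
    "#E69F00",
    "#56B4E9",
    "#009E73",
    "#F0E442",
    "#0072B2",
    "#D55E00",
    "#CC79A7",
    "#999999",
]

MISSING_COLOR = "#FFFFFF"


@dataclass
class Palette:
    name: str
    colors: list[str]

    def __post_init__(self) -> None:
        if not self.colors:
            raise ValidationError("palette must have at least one color")
        for c in self.colors:
            if not _HEX_RE.match(c):
                raise ValidationError(f"invalid hex color {c!r} in palette {self.name!r}")


@dataclass
class Covariate:
    """Named per-label annotation attached to one axis.

    ``values`` maps axis label → category text (discrete) or float
    (continuous; NaN for missing).  ``colors`` is filled in by
    :func:`default_colors` (or set explicitly): a category→hex dict plus
    a ``missing`` key for discrete bars, or a ColorMap for continuous.
    """

    name: str
    axis: str
    kind: str  # discrete | continuous
    values: dict = field(default_factory=dict)
    colors: object = None
    position: int = 0

    def __post_init__(self) -> None:
        _check_axis(self.axis)
        if self.kind not in ("discrete", "continuous"):
            raise ValidationError(f"covariate kind must be discrete or continuous, got {self.kind!r}")

    def categories(self) -> list[str]:
        """Distinct discrete categories in order of first appearance."""
        if self.kind != "discrete":
            raise ValidationError("categories() only applies to discrete covariates")
        seen: list[str] = []
        for v in self.values.values():
            if v is not None and v not in seen:
                seen.append(v)
        return seen

    def value_for(self, label: str):
        return self.values.get(label)

    def to_dict(self) -> dict:
        vals = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in self.values.items()
        }
        colors = self.colors
        if hasattr(colors, "to_dict"):
            colors = {"colormap": colors.to_dict()}
        return {
            "name": self.name,
            "axis": self.axis,
            "kind": self.kind,
            "values": vals,
            "colors": colors,
            "position": self.position,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Covariate":
        values = dict(d["values"])
        if d["kind"] == "continuous":
            values = {k: (np.nan if v is None else float(v)) for k, v in values.items()}
        colors = d.get("colors")
        if isinstance(colors, dict) and "colormap" in colors:
            from chmforge.spec import ColorMap

            colors = ColorMap.from_dict(colors["colormap"])
        return cls(
            name=d["name"],
            axis=d["axis"],
            kind=d["kind"],
            values=values,
            colors=colors,
            position=int(d.get("position", 0)),
        )


def _split_line(line: str) -> list[str]:
    if "\t" in line:
        return next(csv.reader([line], delimiter="\t"))
    return next(csv.reader([line]))


def parse_covariate(
    path: str,
    axis: str,
    kind: str,
    matrix_labels: list[str],
    name: str | None = None,
) -> Covariate:
    """Parse a two-column covariate file against the matrix's labels.

    Entries whose label is absent from ``matrix_labels`` are dropped
    with a warning; matrix labels absent from the file get a missing
    value.  For continuous covariates non-numeric values become missing
    with a warning; a leading header line (second field non-numeric) is
    skipped automatically.
    """
    _check_axis(axis)
    if not os.path.exists(path):
        raise IOError(f"covariate file {path!r} does not exist")
    with open(path, encoding="utf-8-sig") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"covariate file {path!r} is empty")
    rows = [_split_line(ln) for ln in lines]
    for r in rows:
        if len(r) < 2:
            raise ValidationError(
                f"covariate file {path!r}: expected two fields per line, got {r!r}"
            )
    label_set = set(matrix_labels)
    # header detection: first line, non-numeric value, label not in the matrix
    if (
        kind == "continuous"
        and rows
        and not _is_number(rows[0][1])
        and rows[0][0].strip() not in label_set
    ):
        rows = rows[1:]
    values: dict = {}
    for r in rows:
        lab, raw = r[0].strip(), r[1].strip()
        if lab not in label_set:
            warnings.warn(
                f"covariate {name or path}: label {lab!r} not in matrix; entry dropped"
            )
            continue
        if kind == "continuous":
            if _is_number(raw):
                values[lab] = float(raw)
            else:
                warnings.warn(
                    f"covariate {name or path}: non-numeric value {raw!r} for "
                    f"{lab!r}; set to missing"
                )
                values[lab] = np.nan
        else:
            values[lab] = raw
    for lab in matrix_labels:
        values.setdefault(lab, np.nan if kind == "continuous" else None)
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return Covariate(name=name, axis=axis, kind=kind, values=values)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def default_colors(c: Covariate, p: Palette | None = None) -> Covariate:
    """Assign default colors: palette cycling for discrete categories (in
    order of first appearance), a min→max two-point ColorMap for
    continuous.  Deterministic for a given covariate + palette."""
    if p is None:
        p = Palette("default", list(DEFAULT_PALETTE_COLORS))
    if c.kind == "discrete":
        mapping = {
            cat: p.colors[i % len(p.colors)] for i, cat in enumerate(c.categories())
        }
        mapping["missing"] = MISSING_COLOR
        c.colors = mapping
    else:
        from chmforge.spec import ColorMap

        nums = [v for v in c.values.values() if v is not None and not np.isnan(v)]
        lo = min(nums) if nums else 0.0
        hi = max(nums) if nums else 1.0
        if hi <= lo:
            hi = lo + 1.0
        c.colors = ColorMap(
            breakpoints=[lo, hi],
            colors=[p.colors[0], p.colors[min(1, len(p.colors) - 1)]],
            missing_color=MISSING_COLOR,
        )
    return c


def reorder_bars(bars: list[Covariate], order: list[int]) -> list[Covariate]:
    """Reorder covariate bars; ``order`` must be a permutation of their
    indices.  Positions are renumbered to the new order."""
    if sorted(order) != list(range(len(bars))):
        raise ValidationError(
            f"order {order!r} is not a permutation of 0..{len(bars) - 1}"
        )
    out = [bars[i] for i in order]
    for pos, bar in enumerate(out):
        bar.position = pos
    return out


def extract_embedded_covariates(
    raw_grid: list[list[object]],
    region,
    covariate_rows: list[int] = (),
    covariate_cols: list[int] = (),
) -> tuple[list[Covariate], "object"]:
    """Lift annotation rows/columns embedded in an uploaded matrix.

    ``covariate_rows`` are grid row indices strictly between the column-
    label row and the data origin; each becomes a column-axis covariate
    named by its cell in the row-label column.  ``covariate_cols`` work
    symmetrically for row-axis covariates.  The remaining grid is parsed
    as the LabeledMatrix.  Kind is auto-proposed: all-numeric values →
    continuous, otherwise discrete.
    """
    from chmforge.matrix import RegionSpec
    from chmforge.matrix_io import grid_to_matrix

    r0, c0 = region.data_origin
    for r in covariate_rows:
        if not (region.label_row_index < r < r0):
            raise ValidationError(
                f"embedded covariate row {r} must lie between the label row "
                f"({region.label_row_index}) and the data origin row ({r0})"
            )
    for c in covariate_cols:
        if not (region.label_col_index < c < c0):
            raise ValidationError(
                f"embedded covariate column {c} must lie between the label column "
                f"({region.label_col_index}) and the data origin column ({c0})"
            )
    col_labels = [
        "" if v is None else str(v).strip() for v in raw_grid[region.label_row_index][c0:]
    ]
    row_labels = [
        "" if row[region.label_col_index] is None else str(row[region.label_col_index]).strip()
        for row in raw_grid[r0:]
    ]
    covs: list[Covariate] = []
    for r in covariate_rows:
        cells = ["" if v is None else str(v).strip() for v in raw_grid[r][c0:]]
        covs.append(_embedded_cov(str(raw_grid[r][region.label_col_index]), "col", col_labels, cells))
    for c in covariate_cols:
        cells = ["" if row[c] is None else str(row[c]).strip() for row in raw_grid[r0:]]
        covs.append(_embedded_cov(str(raw_grid[region.label_row_index][c]), "row", row_labels, cells))
    keep_rows = [i for i in range(len(raw_grid)) if i not in set(covariate_rows)]
    width = len(raw_grid[0]) if raw_grid else 0
    keep_cols = [j for j in range(width) if j not in set(covariate_cols)]
    sub = [[raw_grid[i][j] for j in keep_cols] for i in keep_rows]
    new_region = RegionSpec(
        label_row_index=region.label_row_index,
        label_col_index=region.label_col_index,
        data_origin=(r0 - sum(1 for r in covariate_rows if r < r0),
                     c0 - sum(1 for c in covariate_cols if c < c0)),
    )
    matrix = grid_to_matrix(sub, new_region)
    for pos, cov in enumerate(covs):
        cov.position = pos
    return covs, matrix


def _embedded_cov(name: str, axis: str, labels: list[str], cells: list[str]) -> Covariate:
    numeric = all(_is_number(c) for c in cells if c != "")
    kind = "continuous" if numeric and any(c != "" for c in cells) else "discrete"
    values: dict = {}
    for lab, cell in zip(labels, cells):
        if kind == "continuous":
            values[lab] = float(cell) if cell != "" else np.nan
        else:
            values[lab] = cell if cell != "" else None
    return Covariate(name=name.strip(), axis=axis, kind=kind, values=values)


# ---------------------------------------------------------------------------
# palette store


class PaletteStore:
    """Named palettes persisted as a local JSON document, seeded with the
    colorblind-safe default palette."""

    def __init__(self, path: str):
        self.path = path
        self.palettes: dict[str, Palette] = {}
        if os.path.exists(path):
            with open(path, encoding="utf-8") as fh:
                doc = json.load(fh)
            for name, colors in doc.get("palettes", {}).items():
                self.palettes[name] = Palette(name, colors)
        if "default" not in self.palettes:
            self.palettes["default"] = Palette("default", list(DEFAULT_PALETTE_COLORS))

    def get(self, name: str) -> Palette:
        if name not in self.palettes:
            raise ValidationError(f"no palette named {name!r} in {self.path}")
        return self.palettes[name]

    def save_palette(self, p: Palette) -> None:
        self.palettes[p.name] = p
        self.flush()

    def flush(self) -> None:
        doc = {"palettes": {name: p.colors for name, p in sorted(self.palettes.items())}}
        with open(self.path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
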