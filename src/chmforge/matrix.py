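"""Core labeled-matrix container.

Missing cells are represented by NaN in a float64 array.  ``n_invalid``
counts cells whose source text was neither numeric nor a recognized
missing token; they are stored as missing but reported separately so the
summary panel can flag dirty input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from chmforge.errors import ValidationError

#: tokens treated as intentionally-missing on input (case-insensitive)
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})


@dataclass
class LabeledMatrix:
    """Numeric matrix with row/column label vectors and NaN for missing."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray  # float64, shape (n_rows, n_cols), NaN == missing
    n_invalid: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("matrix values must be 2-dimensional")
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError(
                f"label lengths ({len(self.row_labels)}, {len(self.col_labels)}) "
                f"do not match value shape {self.values.shape}"
            )
        self.row_labels = [str(x) for x in self.row_labels]
        self.col_labels = [str(x) for x in self.col_labels]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def labels(self, axis: str) -> list[str]:
        _check_axis(axis)
        return self.row_labels if axis == "row" else self.col_labels

    def copy(self) -> "LabeledMatrix":
        return replace(
            self,
            row_labels=list(self.row_labels),
            col_labels=list(self.col_labels),
            values=self.values.copy(),
        )

    def equals(self, other: "LabeledMatrix") -> bool:
        """Cell-for-cell equality including the missing pattern and labels."""
        if self.row_labels != other.row_labels or self.col_labels != other.col_labels:
            return False
        a, b = self.values, other.values
        if a.shape != b.shape:
            return False
        return bool(np.array_equal(a, b, equal_nan=True))

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass(frozen=True)
class RegionSpec:
    """Where labels and data live in a raw parsed grid (all 0-based).

    The default assumes the first row holds column labels and the first
    column holds row labels, with data starting at (1, 1).
    """

    label_row_index: int = 0
    label_col_index: int = 0
    data_origin: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        r, c = self.data_origin
        if not (r > self.label_row_index and c > self.label_col_index):
            raise ValidationError(
                "data origin must lie strictly below the label row and strictly "
                f"right of the label column (got origin {self.data_origin}, "
                f"label row {self.label_row_index}, label col {self.label_col_index})"
            )


def _check_axis(axis: str) -> None:
    if axis not in ("row", "col"):
        raise ValidationError(f"axis must be 'row' or 'col', got {axis!r}")


def parse_cell(token: object) -> tuple[float, bool]:
    """Parse one raw cell into (value, is_invalid).

    Numeric strings and numbers parse to their value; recognized missing
    tokens and None parse to NaN without being invalid; anything else is
    NaN and invalid.
    """
    if token is None:
        return np.nan, False
    if isinstance(token, (int, float)) and not isinstance(token, bool):
        v = float(token)
        return (v, False) if np.isfinite(v) else (np.nan, False)
    s = str(token).strip()
    if s.lower() in MISSING_TOKENS:
        return np.nan, False
    try:
        v = float(s)
    except ValueError:
        return np.nan, True
    if not np.isfinite(v):
        return np.nan, False
    return v, False
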