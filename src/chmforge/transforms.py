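"""Transform/filter engine with a replayable history.

Every operation is pure (consumes and produces a :class:`LabeledMatrix`)
and is addressable by name through a :class:`TransformStep`, so any
sequence of edits can be serialized, replayed against the preserved
original matrix, and undone by replaying a prefix.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chmforge.errors import ValidationError
from chmforge.matrix import LabeledMatrix, _check_axis
from chmforge.matrix_io import dedupe_labels

DEFAULT_SIZE_LIMIT = 5000
DEFAULT_BINS = 10


# ---------------------------------------------------------------------------
# individual operations


def threshold_na(m: LabeledMatrix, cutoff: float) -> LabeledMatrix:
    """Set every cell strictly below ``cutoff`` to missing.

    Cells equal to the cutoff survive ("below" is strict).
    """
    if not math.isfinite(cutoff):
        raise ValidationError("threshold cutoff must be finite")
    out = m.copy()
    with np.errstate(invalid="ignore"):
        out.values[out.values < cutoff] = np.nan
    return out


def log_transform(m: LabeledMatrix, base: float = 10.0) -> LabeledMatrix:
    """Log-transform all positive cells; non-positive cells become missing.

    Making zeros and negatives missing (rather than erroring) lets a later
    missing-data filter clean them up, matching the forgiving builder flow.
    """
    if not (base > 0) or base == 1:
        raise ValidationError(f"log base must be positive and != 1, got {base}")
    out = m.copy()
    v = out.values
    with np.errstate(invalid="ignore", divide="ignore"):
        nonpos = v <= 0
        v[nonpos] = np.nan
        out.values = np.log(v) / math.log(base)
    return out


def mean_center(m: LabeledMatrix, axis: str) -> LabeledMatrix:
    """Subtract each row's (or column's) mean over its non-missing cells."""
    _check_axis(axis)
    out = m.copy()
    ax = 1 if axis == "row" else 0
    with np.errstate(invalid="ignore"):
        means = np.nanmean(
            np.where(np.all(np.isnan(out.values), axis=ax, keepdims=True), 0.0, out.values),
            axis=ax,
            keepdims=True,
        )
    # all-missing vectors contribute mean 0, i.e. stay unchanged
    out.values = out.values - means
    return out


def transpose(m: LabeledMatrix) -> LabeledMatrix:
    """Exchange rows and columns, values and labels alike."""
    return LabeledMatrix(
        row_labels=list(m.col_labels),
        col_labels=list(m.row_labels),
        values=m.values.T.copy(),
        n_invalid=m.n_invalid,
    )


def correlation(m: LabeledMatrix, axis: str = "row", method: str = "pearson") -> LabeledMatrix:
    """Pairwise Pearson correlation among the vectors on one axis.

    Uses pairwise-complete observations.  A pair whose shared positions
    have zero variance yields a missing cell.
    """
    _check_axis(axis)
    if method != "pearson":
        raise ValidationError(f"unsupported correlation method {method!r}")
    labels = m.labels(axis)
    if len(labels) < 2:
        raise ValidationError("correlation needs at least 2 vectors on the axis")
    vecs = m.values if axis == "row" else m.values.T
    corr = pd.DataFrame(vecs.T).corr(method="pearson", min_periods=2).to_numpy()
    np.fill_diagonal(corr, 1.0)
    return LabeledMatrix(list(labels), list(labels), corr, n_invalid=m.n_invalid)


def replace_missing(m: LabeledMatrix, value: float, strategy: str = "constant") -> LabeledMatrix:
    """Replace every missing cell by a constant."""
    if strategy != "constant":
        raise ValidationError(f"unsupported replace strategy {strategy!r}")
    if not math.isfinite(value):
        raise ValidationError("replacement value must be finite")
    out = m.copy()
    out.values[np.isnan(out.values)] = value
    return out


def filter_missing(m: LabeledMatrix, axis: str, max_pct: float) -> LabeledMatrix:
    """Drop vectors whose missing percentage strictly exceeds ``max_pct``.

    The percentage is computed against the full axis length, and the
    boundary is non-strict: a row at exactly ``max_pct`` is retained.
    """
    _check_axis(axis)
    if not (0 <= max_pct <= 100):
        raise ValidationError(f"max_pct must be in [0, 100], got {max_pct}")
    ax = 1 if axis == "row" else 0
    total = m.values.shape[ax]
    pct = 100.0 * np.isnan(m.values).sum(axis=ax) / max(total, 1)
    keep = np.flatnonzero(pct <= max_pct)
    if keep.size == 0 and m.labels(axis):
        raise ValidationError(
            f"missing-data filter at {max_pct}% would remove every {axis}"
        )
    return _take(m, axis, keep)


def axis_sd(m: LabeledMatrix, axis: str) -> np.ndarray:
    """Sample standard deviation (ddof=1) per vector over non-missing
    cells; vectors with < 2 non-missing cells get SD 0."""
    ax = 1 if axis == "row" else 0
    counts = (~np.isnan(m.values)).sum(axis=ax)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(m.values, axis=ax, ddof=1)
    sd = np.where(counts < 2, 0.0, sd)
    return np.nan_to_num(sd, nan=0.0)


def filter_top_sd(m: LabeledMatrix, axis: str, keep_n: int) -> LabeledMatrix:
    """Keep the ``keep_n`` vectors with highest standard deviation.

    Survivors keep their original relative order; ties at the boundary
    are broken in favor of the earlier vector, so the result is
    deterministic.  A no-op when the axis already has <= ``keep_n``.
    """
    _check_axis(axis)
    keep_n = int(keep_n)
    if keep_n < 1:
        raise ValidationError(f"keep_n must be >= 1, got {keep_n}")
    n = len(m.labels(axis))
    if n <= keep_n:
        return m.copy()
    sd = axis_sd(m, axis)
    ranked = np.argsort(-sd, kind="stable")[:keep_n]  # stable: earlier index wins ties
    keep = np.sort(ranked)
    return _take(m, axis, keep)


def _take(m: LabeledMatrix, axis: str, idx: np.ndarray) -> LabeledMatrix:
    if axis == "row":
        return LabeledMatrix(
            [m.row_labels[i] for i in idx], list(m.col_labels), m.values[idx], m.n_invalid
        )
    return LabeledMatrix(
        list(m.row_labels), [m.col_labels[i] for i in idx], m.values[:, idx], m.n_invalid
    )


# ---------------------------------------------------------------------------
# step vocabulary

_ACTIONS = {
    "threshold_na": lambda m, p: threshold_na(m, float(p["cutoff"])),
    "log": lambda m, p: log_transform(m, float(p.get("base", 10))),
    "mean_center_row": lambda m, p: mean_center(m, "row"),
    "mean_center_col": lambda m, p: mean_center(m, "col"),
    "transpose": lambda m, p: transpose(m),
    "correlation": lambda m, p: correlation(
        m, p.get("axis", "row"), p.get("method", "pearson")
    ),
    "replace_missing": lambda m, p: replace_missing(m, float(p["value"])),
    "filter_missing_row": lambda m, p: filter_missing(m, "row", float(p["max_pct"])),
    "filter_missing_col": lambda m, p: filter_missing(m, "col", float(p["max_pct"])),
    "filter_sd_row": lambda m, p: filter_top_sd(m, "row", int(p["keep_n"])),
    "filter_sd_col": lambda m, p: filter_top_sd(m, "col", int(p["keep_n"])),
    "dedupe": lambda m, p: dedupe_labels(m, p["axis"], p.get("mode", "rename")),
}


@dataclass(frozen=True)
class TransformStep:
    """One named, serializable edit of the working matrix."""

    action: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.action not in _ACTIONS:
            raise ValidationError(
                f"unknown transform action {self.action!r}; "
                f"known: {sorted(_ACTIONS)}"
            )

    def apply(self, m: LabeledMatrix) -> LabeledMatrix:
        return _ACTIONS[self.action](m, self.params)

    def serialize(self) -> str:
        """``action<TAB>key=value;key=value`` with JSON-encoded values."""
        parts = ";".join(
            f"{k}={json.dumps(self.params[k])}" for k in sorted(self.params)
        )
        return f"{self.action}\t{parts}"

    @classmethod
    def deserialize(cls, line: str) -> "TransformStep":
        action, _, rest = line.partition("\t")
        params = {}
        if rest.strip():
            for kv in rest.split(";"):
                k, _, v = kv.partition("=")
                params[k] = json.loads(v)
        return cls(action.strip(), params)


def replay(original: LabeledMatrix, history: list[TransformStep]) -> LabeledMatrix:
    """Apply ``history`` to a copy of ``original`` in order."""
    m = original.copy()
    for step in history:
        m = step.apply(m)
    return m


@dataclass
class MatrixSession:
    """Preserved original + working copy + ordered transform history.

    The invariant ``working == replay(original, history)`` holds after
    every :meth:`apply_step` / :meth:`undo_to`; undo is implemented by
    replaying a history prefix against the preserved original.
    """

    original: LabeledMatrix
    working: LabeledMatrix = None  # type: ignore[assignment]
    history: list[TransformStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.working is None:
            self.working = self.original.copy()

    def apply_step(self, step: TransformStep) -> "MatrixSession":
        """Apply one step; on failure the session is unchanged."""
        new_working = step.apply(self.working)  # may raise; session untouched
        self.working = new_working
        self.history.append(step)
        return self

    def undo_to(self, k: int) -> "MatrixSession":
        """Truncate history to its first ``k`` steps and replay."""
        if not (0 <= k <= len(self.history)):
            raise ValidationError(
                f"undo index {k} out of range 0..{len(self.history)}"
            )
        self.history = self.history[:k]
        self.working = replay(self.original, self.history)
        return self


# ---------------------------------------------------------------------------
# summary statistics


@dataclass
class SummaryStats:
    n_rows: int
    n_cols: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    n_invalid: int
    n_missing: int
    flags: list[str]


def summarize(
    m: LabeledMatrix, n_bins: int = DEFAULT_BINS, size_limit: int = DEFAULT_SIZE_LIMIT
) -> SummaryStats:
    """Counts, a histogram of non-missing values, and advisory flags.

    Flags warn about (not enforce) conditions the build pipeline cares
    about: the clustering size gate and duplicate labels.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    vals = m.values[~np.isnan(m.values)]
    if vals.size == 0:
        edges, counts = np.array([0.0, 1.0]), np.array([0])
    elif np.min(vals) == np.max(vals):
        v = float(vals[0])
        edges, counts = np.array([v, v]), np.array([vals.size])
    else:
        counts, edges = np.histogram(vals, bins=n_bins)
    flags = []
    if m.n_rows + m.n_cols > size_limit:
        flags.append(
            f"size: {m.n_rows} rows + {m.n_cols} columns exceeds the "
            f"clustering limit of {size_limit}; filter before clustering"
        )
    for axis in ("row", "col"):
        labs = m.labels(axis)
        if len(set(labs)) != len(labs):
            flags.append(f"duplicate {axis} labels present; consider a dedupe step")
    if m.n_invalid:
        flags.append(f"{m.n_invalid} invalid cells were set to missing on import")
    return SummaryStats(
        n_rows=m.n_rows,
        n_cols=m.n_cols,
        bin_edges=edges,
        bin_counts=counts,
        n_invalid=m.n_invalid,
        n_missing=int(np.isnan(m.values).sum()),
        flags=flags,
    )
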