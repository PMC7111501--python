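"""Seeded generators for expression-like test data.

Emulates the matrices the builder typically receives: positive
log-normally distributed abundance values with optional planted
row/column cluster structure, a zero-inflated fraction (drop-outs),
injected missing and invalid tokens, optional duplicate labels, and
matching discrete/continuous covariate files.  Everything is driven by
an explicit seed, so fixtures are reproducible and self-contained.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from chmforge.matrix import LabeledMatrix


@dataclass
class ExpressionFixture:
    """A generated matrix plus ground truth about its construction."""

    grid: list[list[str]]  # raw cell tokens incl. labels, NA and invalid tokens
    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray  # clean numeric truth (NaN where missing/invalid was injected)
    row_clusters: np.ndarray  # planted row-cluster id per row
    col_clusters: np.ndarray  # planted column-cluster id per column
    n_injected_invalid: int = 0

    def labeled_matrix(self) -> LabeledMatrix:
        return LabeledMatrix(
            list(self.row_labels), list(self.col_labels), self.values.copy()
        )

    def write(self, path: str) -> str:
        """Write the raw grid in the dialect implied by the extension
        (.txt tab-delimited, .csv, .xlsx)."""
        ext = os.path.splitext(path)[1].lower()
        if ext == ".csv":
            with open(path, "w", encoding="utf-8", newline="") as fh:
                import csv

                csv.writer(fh).writerows(self.grid)
        elif ext in (".txt", ".tsv"):
            with open(path, "w", encoding="utf-8", newline="") as fh:
                for row in self.grid:
                    fh.write("\t".join(row) + "\n")
        elif ext == ".xlsx":
            import openpyxl

            wb = openpyxl.Workbook()
            ws = wb.active
            for row in self.grid:
                ws.append([_maybe_number(c) for c in row])
            wb.save(path)
        else:
            raise ValueError(f"unsupported fixture extension {ext!r}")
        return path


def _maybe_number(tok: str):
    try:
        return float(tok)
    except ValueError:
        return tok


def expression_matrix(
    n_rows: int = 2000,
    n_cols: int = 100,
    n_row_clusters: int = 1,
    n_col_clusters: int = 1,
    effect_sd: float = 1.0,
    noise_sd: float = 0.5,
    zero_frac: float = 0.10,
    missing_frac: float = 0.01,
    invalid_frac: float = 0.005,
    duplicate_col_labels: int = 0,
    duplicate_row_labels: int = 0,
    seed: int = 0,
) -> ExpressionFixture:
    """Generate an expression-like matrix as a raw text grid.

    Values are log-normal: log10 of each cell is a per-row baseline
    (N(2, 1)) plus a planted cluster effect (N(0, effect_sd) per
    row-cluster × column-cluster block) plus noise (N(0, noise_sd)).
    ``zero_frac`` of cells are zeroed (drop-outs, removable by a
    threshold step), ``missing_frac`` become "NA" tokens and
    ``invalid_frac`` become unparseable tokens.
    """
    rng = np.random.default_rng(seed)
    row_clusters = rng.integers(0, n_row_clusters, size=n_rows)
    col_clusters = np.sort(rng.integers(0, n_col_clusters, size=n_cols))
    baseline = rng.normal(2.0, 1.0, size=n_rows)
    block = rng.normal(0.0, effect_sd, size=(n_row_clusters, n_col_clusters))
    log10v = (
        baseline[:, None]
        + block[row_clusters[:, None], col_clusters[None, :]]
        + rng.normal(0.0, noise_sd, size=(n_rows, n_cols))
    )
    # 6 decimals: realistic for exported tables, and short enough that the
    # value survives every dialect (xlsx keeps 15 significant digits)
    values = np.round(np.power(10.0, log10v), 6)

    zero_mask = rng.random((n_rows, n_cols)) < zero_frac
    values[zero_mask] = 0.0
    missing_mask = rng.random((n_rows, n_cols)) < missing_frac
    invalid_mask = (rng.random((n_rows, n_cols)) < invalid_frac) & ~missing_mask

    row_labels = [f"gene_{i + 1}" for i in range(n_rows)]
    col_labels = [f"sample_{j + 1}" for j in range(n_cols)]
    for i in range(min(duplicate_row_labels, n_rows - 1)):
        row_labels[2 * i + 1] = row_labels[2 * i]
    for j in range(min(duplicate_col_labels, n_cols - 1)):
        col_labels[2 * j + 1] = col_labels[2 * j]

    grid = [[""] + col_labels]
    for i in range(n_rows):
        row = [row_labels[i]]
        for j in range(n_cols):
            if missing_mask[i, j]:
                row.append("NA")
            elif invalid_mask[i, j]:
                row.append("#VALUE!")
            else:
                row.append(repr(float(values[i, j])))
        grid.append(row)

    truth = values.copy()
    truth[missing_mask | invalid_mask] = np.nan
    return ExpressionFixture(
        grid=grid,
        row_labels=row_labels,
        col_labels=col_labels,
        values=truth,
        row_clusters=row_clusters,
        col_clusters=col_clusters,
        n_injected_invalid=int(invalid_mask.sum()),
    )


def clustered_matrix(
    n_rows: int = 50,
    n_cols: int = 80,
    k: int = 4,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[LabeledMatrix, np.ndarray]:
    """Well-separated planted column clusters for recovery tests.

    Each column belongs to one of ``k`` clusters; cluster centers are
    N(0, separation) per row, columns scatter N(center, noise_sd).
    Returns the matrix and the planted assignment (one id per column).
    Every cluster is guaranteed at least one member.
    """
    rng = np.random.default_rng(seed)
    if k > n_cols:
        raise ValueError("k cannot exceed n_cols")
    assign = np.concatenate([np.arange(k), rng.integers(0, k, size=n_cols - k)])
    centers = rng.normal(0.0, separation, size=(n_rows, k))
    values = centers[:, assign] + rng.normal(0.0, noise_sd, size=(n_rows, n_cols))
    m = LabeledMatrix(
        [f"gene_{i + 1}" for i in range(n_rows)],
        [f"sample_{j + 1}" for j in range(n_cols)],
        values,
    )
    return m, assign


def covariate_file(
    path: str,
    labels: list[str],
    kind: str = "discrete",
    categories: tuple[str, ...] = ("Smoker", "Non-smoker"),
    value_range: tuple[float, float] = (40.0, 80.0),
    coverage: float = 1.0,
    seed: int = 0,
    header: bool = False,
    delimiter: str = "\t",
) -> str:
    """Write a two-column covariate file for a subset of ``labels``."""
    rng = np.random.default_rng(seed)
    lines = []
    if header:
        lines.append(delimiter.join(["id", "value"]))
    for lab in labels:
        if rng.random() > coverage:
            continue
        if kind == "discrete":
            val = categories[int(rng.integers(0, len(categories)))]
        else:
            val = repr(float(rng.uniform(*value_range)))
        lines.append(f"{lab}{delimiter}{val}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def use_case_steps() -> list[tuple[str, dict]]:
    """The six-step transform recipe exercised throughout the docs:
    dedupe column labels, threshold tiny values to missing, log10,
    mean-center rows, drop rows over 50% missing, keep the 500
    highest-SD rows."""
    return [
        ("dedupe", {"axis": "col", "mode": "rename"}),
        ("threshold_na", {"cutoff": 0.00001}),
        ("log", {"base": 10}),
        ("mean_center_row", {}),
        ("filter_missing_row", {"max_pct": 50}),
        ("filter_sd_row", {"keep_n": 500}),
    ]


def main() -> None:
    """``chmforge-fixtures``: write a seeded fixture matrix (+ optional
    covariates) to disk."""
    import click

    @click.command()
    @click.option("--out", required=True, help="matrix output path (.txt/.csv/.xlsx)")
    @click.option("--rows", default=2000, show_default=True)
    @click.option("--cols", default=100, show_default=True)
    @click.option("--row-clusters", default=1, show_default=True)
    @click.option("--col-clusters", default=1, show_default=True)
    @click.option("--missing-frac", default=0.01, show_default=True)
    @click.option("--invalid-frac", default=0.005, show_default=True)
    @click.option("--duplicate-cols", default=0, show_default=True)
    @click.option("--seed", default=0, show_default=True)
    @click.option(
        "--covariate",
        "covariates",
        multiple=True,
        help="write a covariate file; format NAME:KIND:PATH (kind discrete|continuous)",
    )
    def cmd(out, rows, cols, row_clusters, col_clusters, missing_frac, invalid_frac, duplicate_cols, seed, covariates):
        fx = expression_matrix(
            n_rows=rows,
            n_cols=cols,
            n_row_clusters=row_clusters,
            n_col_clusters=col_clusters,
            missing_frac=missing_frac,
            invalid_frac=invalid_frac,
            duplicate_col_labels=duplicate_cols,
            seed=seed,
        )
        fx.write(out)
        click.echo(f"wrote {rows}x{cols} matrix to {out}")
        for i, spec_str in enumerate(covariates):
            name, kind, path = spec_str.split(":", 2)
            covariate_file(path, fx.col_labels, kind=kind, seed=seed + 1 + i)
            click.echo(f"wrote {kind} covariate {name!r} to {path}")

    cmd()


if __name__ == "__main__":
    main()
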