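# chmforge

**Scriptable construction of clustered heat maps** — from a raw numeric
matrix to a formatted, annotated, exactly-reproducible heat map, as a
Python library and a thin command-line tool.

Clustered heat maps (CHMs) are the workhorse visualization of
genome-scale profiling: rows and columns of a data matrix are reordered
by agglomerative hierarchical clustering, values are color-encoded, and
flanking dendrograms plus covariate bars expose structure among samples
and features. Producing a good one is rarely a linear process — it
means cleaning invalid values, filtering and normalizing, trying
clustering options, attaching clinical annotations and tuning colors.
`chmforge` packages that whole workflow for people who want it
scriptable, testable and reproducible: every chosen option lands in a
creation log from which the map can be rebuilt byte-for-byte.

## What it does

* **Matrix ingestion** — tab-delimited text, CSV (RFC-4180) and Excel
  `.xlsx` parse to the same labeled matrix; configurable label/data
  regions; duplicate-label repair (`A, A, B → A, A_2, B`); non-numeric
  cells become missing and are counted as invalid.
* **Transform/filter engine** — threshold-to-missing, log transform,
  row/column mean centering, transpose, Pearson correlation matrices,
  missing-value replacement, missing-percentage filters, top-N
  standard-deviation filters. The original matrix is preserved; the
  working matrix always equals the replay of the recorded history, so
  any prefix can be restored (undo).
* **Clustering** — agglomerative hierarchical clustering with
  {ward, complete, average, single} linkage × {euclidean, manhattan,
  correlation} distance (Ward in ward.D2 form, i.e. heights are the
  Lance–Williams recurrence on squared distances), pairwise-complete
  handling of missing values, deterministic leaf ordering, Newick
  export, seeded random or original ordering, a 5,000 rows+columns
  size gate, and discrete covariates cut from the top *k* dendrogram
  branches.
* **Covariate bars** — two-column annotation files (discrete or
  continuous), covariates embedded in the uploaded matrix, cyclic
  palette coloring (colorblind-safe default), bar reordering, a local
  JSON palette store.
* **Formatting** — piecewise-linear colormaps over strictly increasing
  breakpoints (default: blue–white–red at the 5th/50th/95th
  percentiles), label link-out types, gaps between sub-groups, top
  items, dendrogram display modes.
* **Outputs** — a deterministic `.ngchm` zip archive around a
  `heatmapProperties.json` options document (lossless round trip), a
  3-page PDF (summary, zoomed detail, legends + metadata), and the
  creation log.

## Worked example

```python
from chmforge import Builder, OrderSpec
from chmforge.fixtures import expression_matrix, covariate_file

fx = expression_matrix(n_rows=300, n_cols=40, duplicate_col_labels=1, seed=5)
matrix = fx.write("expression.txt")
stage = covariate_file("stage.txt", fx.col_labels, kind="discrete",
                       categories=("I", "II", "III"), seed=6)

b = Builder(name="Demo map")
b.import_matrix(matrix)
b.transform("dedupe", axis="col", mode="rename")
b.transform("threshold_na", cutoff=0.00001)   # tiny values -> missing
b.transform("log", base=10)
b.transform("mean_center_row")
b.transform("filter_sd_row", keep_n=100)      # keep most-variable genes
b.set_order("row", OrderSpec(mode="cluster", linkage="ward", distance="euclidean"))
b.set_order("col", OrderSpec(mode="cluster", linkage="average", distance="correlation"))
b.add_top_branch_covariate("col", 3)          # top 3 dendrogram branches
b.add_covariate(stage, "col", "discrete", name="stage")
paths = b.write("out")
```

This prints (via `python examples/04_build_archive_and_pdf.py`):

```
outputs: {'ngchm': 'map.ngchm', 'pdf': 'map.pdf', 'log': 'map_creation_log.txt'}
archive members: ['covariates/00_col_stage.tsv', 'covariates/01_col_Top_3_Branches.tsv',
 'creation_log.txt', 'dendrogram_col.newick', 'dendrogram_row.newick',
 'heatmapProperties.json', 'manifest.json', 'matrix.tsv']
raster: 100 x 42 display cells (matrix 100 x 40 + gap strips)
creation log: 13 events; colormap breakpoints ['-0.90', '-0.00', '0.90']
```

The 100 retained rows and 40 samples are displayed in dendrogram leaf
order; the two extra raster columns are the gap strip; the breakpoints
are the 5th/50th/95th percentiles of the mean-centered log values. The
`examples/` directory has one short script per capability, including
exact replay:

```python
from chmforge import CreationLog, replay, write_ngchm
log = CreationLog.load("out/map_creation_log.txt")
rebuilt = replay("expression.txt", log, covariate_files={"stage.txt": "stage.txt"})
write_ngchm(rebuilt, "replayed.ngchm")   # byte-identical to out/map.ngchm
```

The same workflow is available from the shell (`chmforge import`,
`transform`, `cluster`, `covariate`, `format`, `build`, `replay`;
`chmforge-fixtures` generates seeded demo data).

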