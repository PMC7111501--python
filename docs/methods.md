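# Methods

This note documents the models, conventions and numerical choices
behind `chmforge`, and what its synthetic test data does and does not
establish about real data.

## The pipeline

A build proceeds through the classic CHM stages: parse a labeled
numeric matrix; clean and normalize it with an ordered sequence of
transforms; order rows and columns (clustering, original order, or a
seeded shuffle); attach covariate bars; choose formatting; emit the
archive, PDF and creation log. Two invariants anchor everything:

1. **Session invariant.** The original matrix is immutable; the working
   matrix always equals the replay of the recorded transform history
   against the original. Undo *is* replay of a history prefix — there
   is no inverse-operation bookkeeping to drift out of sync.
2. **Provenance invariant.** Every option that can affect an output
   byte is routed through one event dispatcher and recorded in the
   creation log. Combined with a deterministic archive writer, the
   original input plus the log reproduce the `.ngchm` byte-for-byte.

## Matrix model and parsing

Cells are float64; missing is NaN. On input, the tokens `""`, `NA`,
`NaN`, `null` (case-insensitive) are *missing*; any other non-numeric
token is *invalid* — it also becomes missing but is counted separately
and surfaced in the summary flags, since a nonzero invalid count
usually signals an export problem rather than genuinely absent data.
Non-finite numerics (`inf`) are treated as missing, not invalid. The
three dialects (tab-delimited, CSV, xlsx first worksheet with cached
formula values) parse to identical objects for the same logical table;
note xlsx caps numbers at 15 significant digits, a property of the
format. The writer emits tab-delimited UTF-8 with `NA` sentinels and
`repr` floats, so write→parse is exactly the identity. Labels
containing tabs are not supported.

Duplicate labels are repaired by suffixing occurrence *k* (2-based)
with `_k`, escalating until unique; the first occurrence keeps its
name so covariate files keyed on the original labels still match.

## Transforms

* `threshold_na(cutoff)` — strictly-below semantics: a cell equal to
  the cutoff survives.
* `log(base)` — non-positive cells become missing rather than raising;
  the intended flow is that a later missing-data filter removes rows
  the log invalidated.
* Mean centering subtracts the mean over non-missing cells; an
  all-missing vector is left unchanged. Post-condition: non-missing
  means are 0 to 1e-12.
* Standard deviation uses denominator n−1 over non-missing cells;
  vectors with fewer than two observations get SD 0 and therefore sort
  last. The top-N filter keeps survivors in their original order and
  breaks boundary ties toward the earlier vector (stable argsort), so
  results are deterministic.
* Missing percentage is computed against the full axis length, and the
  filter removes only vectors *strictly* above the threshold — a row at
  exactly 50% survives a 50% filter.
* Correlation uses pairwise-complete observations (Pearson only);
  zero-variance pairs yield missing cells.
* Histograms default to 10 equal-width bins over the observed range;
  constant data collapses to a single bin.

## Distances and clustering

Pairwise distances support missing data by rescaling: for vectors
sharing *s* of *t* positions, Euclidean is
`sqrt(sum_shared (x−y)² · t/s)` and Manhattan `sum_shared |x−y| · t/s`
(the `dist`-style convention); correlation distance is 1 − Pearson over
shared positions. A pair with no shared positions is an error.

Agglomeration is delegated to `scipy.cluster.hierarchy.linkage` on the
precomputed condensed distance matrix. Ward follows **ward.D2**
semantics — the Lance–Williams recurrence applied to squared distances,
the convention of R's `hclust(method="ward.D2")` — which for Euclidean
input equals `sqrt(2|A||B|/(|A|+|B|)) · ‖mean_A − mean_B‖`. The test
suite checks all four linkages × three metrics against a naive O(n³)
pair-scan agglomerator written independently of scipy, on both merge
heights (1e-9) and cophenetic structure.

Leaf ordering is this package's deterministic convention: at every
merge, the subtree containing the smallest original index is placed on
the left. No optimal-leaf-ordering/seriation is attempted. The top-*k*
branch cut removes the k−1 highest merges (valid because heights are
monotone for the supported linkages) and numbers the resulting
clusters "Cluster 1..k" by first appearance in leaf order, i.e. left
to right on the drawn map.

The size gate rejects matrices with rows + columns > 5,000 before
clustering (configurable; clustering cost grows roughly with the
square of the larger dimension). Random ordering uses
`numpy.random.default_rng(seed).permutation`, reproducible for a fixed
seed and numpy generation.

## Covariates and colors

Covariate files are two columns (label, value), tab- or
comma-delimited; a leading header is detected on continuous covariates
when the first line's value is non-numeric *and* its label is not a
matrix label. Entries whose label is not in the matrix are dropped
with a warning; matrix labels absent from the file get the dedicated
missing color (white by default). Default discrete colors cycle
through the Okabe–Ito colorblind-safe palette in order of first
appearance; continuous covariates get a two-point colormap spanning
the observed min..max. Embedded covariates (annotation rows/columns
between the labels and the data region of an uploaded file) are lifted
out before parsing; kind is auto-proposed (all-numeric → continuous)
but an explicit flag wins.

Body colormaps are piecewise-linear in RGB between strictly increasing
breakpoints, clamped at the ends, with channel values rounded half-up.
The default places blue–white–red at the 5th/50th/95th percentiles of
the working matrix; degenerate spreads are widened by a relative 1e-6
to keep breakpoints strictly increasing. Gaps insert fixed-width
(2-cell) background strips into the display layout without touching
data or order.

## Archive and rendering

The `.ngchm` file is a zip with `heatmapProperties.json` (versioned
schema, `schema_version: 1`) holding the full option set, axis
permutations, dendrogram trees and covariate definitions; sibling
entries carry the matrix payload in display order, Newick dendrograms,
per-bar covariate tables, a sha256 manifest, and the canonical
creation log. Entries are written in sorted order with fixed epoch
timestamps, making equal builds byte-identical. Reading restores the
original-orientation matrix by inverting the stored permutations;
unknown extra entries are preserved opaquely. Compatibility with the
production NG-CHM viewer's internal tile format is not attempted.

Rendering goes through an intermediate RGB raster in which cell (i, j)
is exactly `map_color` of the ordered working matrix — the tested
contract — and the PDF draws that raster on page 1 (summary with
dendrograms, covariate bars, top-item callouts), a zoom window with
per-cell labels on page 2 (default top-left 50×50 display cells,
labels truncated with an ellipsis beyond 18 characters), and legends
plus build metadata on page 3.

## Creation log

One event per line: step, action, `key=value` pairs with JSON-encoded
values, and a timestamp. Timestamps are for human readers only; the
canonical serialization embedded in the archive omits them so that
replay comparisons and archive bytes are time-independent. Undo is
recorded as its own event — replaying the log therefore passes through
the same intermediate states, which keeps the replay dispatcher
trivial and the invariant airtight. Step parameter values containing
tabs or semicolons are not supported by the line format.

## Synthetic data

The generator emulates bulk expression tables: log10 values are a
per-row baseline N(2, 1) plus optional planted row×column cluster
block effects N(0, 1) plus noise N(0, 0.5), exponentiated and rounded
to 6 decimals (so every dialect, including 15-digit xlsx, carries them
exactly). By default 10% of cells are zeroed (drop-outs that a 1e-5
threshold turns missing), 1% become `NA` tokens and 0.5% unparseable
tokens; duplicate labels can be injected. The cluster-recovery
generator plants k well-separated column clusters (centers N(0, 6) per
row, scatter N(0, 1)), separation chosen so that within-cluster
distances are strictly below between-cluster distances — recovery by
Ward/Euclidean is then expected, and the tests verify it exactly.

What this does *not* show: robustness to overlapping clusters, batch
effects, heavy-tailed contamination, or non-random missingness —
real-data properties outside the generator's model. The tests
establish the pipeline's algebraic contracts (replay, round trips,
boundary semantics, oracle agreement), not biological validity of any
particular clustering.

## Problem sizes

The test suite and the acceptance script run the use-case recipe at
2000×100, the size gate at 1000×4000 and 4501×500, oracle comparisons
on 100 random matrices with n ≤ 20 (all linkage×metric combinations),
and full builds at roughly 60–80 rows × 24–30 columns — sizes chosen
so the whole suite completes in seconds while still exercising every
code path at the documented parameter values.
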