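"""PDF rendering: summary page, detail page, legends/metadata page.

All cell coloring goes through an intermediate RGB raster in which cell
``(i, j)`` is exactly ``map_color`` of the ordered working matrix at
that display position; tests assert on the raster, and the PDF pages
draw it.  Gaps appear in the raster as fixed-width background strips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.patches import Rectangle

from chmforge.errors import ValidationError
from chmforge.spec import _parse_hex, insert_gaps, map_color

GAP_WIDTH = 2  # blank layout cells per gap
GAP_COLOR = "#FFFFFF"


@dataclass
class RenderLayout:
    """Page geometry and the detail-page zoom window.

    The zoom window is expressed in display cells (after ordering and
    gaps are applied to the axis order, gaps excluded from the count);
    ``None`` bounds default to the top-left 50×50 cells.
    """

    page_size: tuple[float, float] = (11.0, 8.5)
    zoom_rows: tuple[int, int] | None = None
    zoom_cols: tuple[int, int] | None = None
    label_char_budget: int = 18
    dendro_fraction: float = 0.18  # page fraction given to a full dendrogram panel
    covariate_bar_fraction: float = 0.025

    def __post_init__(self) -> None:
        if self.page_size[0] <= 0 or self.page_size[1] <= 0:
            raise ValidationError("page size must be positive")
        for win in (self.zoom_rows, self.zoom_cols):
            if win is not None and not (0 <= win[0] < win[1]):
                raise ValidationError(f"invalid zoom window {win!r}")


def display_slots(order: list[int], gaps: list[int]) -> list[int | None]:
    """Display order expanded with ``None`` slots for gap strips."""
    blocks = insert_gaps(order, gaps)
    slots: list[int | None] = []
    for i, block in enumerate(blocks):
        if i:
            slots.extend([None] * GAP_WIDTH)
        slots.extend(block)
    return slots


def build_raster(build) -> np.ndarray:
    """(H, W, 3) uint8 raster of the heat-map body in display order.

    ``raster[i, j]`` equals ``map_color(colormap, working[r, c])`` for
    the matrix cell displayed at slot (i, j); gap slots get the
    background color.
    """
    cm = build.spec.colormap
    if cm is None:
        raise ValidationError("build has no colormap; run Builder.build()")
    row_slots = display_slots(build.row_perm, build.spec.row_gaps)
    col_slots = display_slots(build.col_perm, build.spec.col_gaps)
    raster = np.zeros((len(row_slots), len(col_slots), 3), dtype=np.uint8)
    gap_rgb = _parse_hex(GAP_COLOR)
    values = build.matrix.values
    # precompute per-column colors row by row (map_color is scalar)
    for i, r in enumerate(row_slots):
        if r is None:
            raster[i, :] = gap_rgb
            continue
        for j, c in enumerate(col_slots):
            raster[i, j] = gap_rgb if c is None else _parse_hex(map_color(cm, values[r, c]))
    return raster


def save_raster_png(build, path: str) -> None:
    """PNG export of the intermediate raster (for docs and debugging)."""
    import PIL.Image

    PIL.Image.fromarray(build_raster(build)).save(path)


# ---------------------------------------------------------------------------
# dendrogram drawing


def _dendro_segments(dend) -> tuple[dict[int, float], list[tuple]]:
    """Node x-positions (in leaf-order units) and U-shaped link segments."""
    pos = {-(leaf + 1): (x + 0.5, 0.0) for x, leaf in enumerate(dend.leaf_order)}
    segments = []
    for k, ((a, b), h) in enumerate(zip(dend.merges, dend.heights), start=1):
        xa, ha = pos[a]
        xb, hb = pos[b]
        segments.append((xa, ha, xa, h))
        segments.append((xb, hb, xb, h))
        segments.append((min(xa, xb), h, max(xa, xb), h))
        pos[k] = ((xa + xb) / 2.0, h)
    return pos, segments


def _draw_dendrogram(ax, dend, horizontal: bool, compact: bool) -> None:
    _, segments = _dendro_segments(dend)
    hmax = max(dend.heights) if dend.heights else 1.0
    scale = 1.0 / hmax if hmax > 0 else 1.0
    for x0, y0, x1, y1 in segments:
        y0, y1 = y0 * scale, y1 * scale
        if compact:
            y0, y1 = min(y0, 0.4), min(y1, 0.4)
        if horizontal:
            ax.plot([x0, x1], [y0, y1], color="black", linewidth=0.6)
        else:
            ax.plot([y0, y1], [x0, x1], color="black", linewidth=0.6)
    ax.set_xticks([])
    ax.set_yticks([])
    for spine in ax.spines.values():
        spine.set_visible(False)


def _truncate(label: str, budget: int) -> str:
    return label if len(label) <= budget else label[: budget - 1] + "…"


def _slot_positions(slots: list[int | None]) -> dict[int, int]:
    """Display index (gaps included) for each matrix index."""
    return {r: i for i, r in enumerate(slots) if r is not None}


# ---------------------------------------------------------------------------
# pages


def render_pdf(build, layout: RenderLayout | None = None, path: str = "map.pdf") -> None:
    """Render a 3-page PDF: summary view, detail view, legends/metadata."""
    layout = layout or RenderLayout()
    raster = build_raster(build)
    with PdfPages(path) as pdf:
        fig = _summary_page(build, raster, layout)
        pdf.savefig(fig)
        plt.close(fig)
        fig = _detail_page(build, layout)
        pdf.savefig(fig)
        plt.close(fig)
        fig = _legend_page(build, layout)
        pdf.savefig(fig)
        plt.close(fig)


def _axis_covariates(build, axis: str):
    bars = [c for c in build.covariates if c.axis == axis]
    order = build.spec.covariate_order.get(axis) or []
    if order:
        by_name = {c.name: c for c in bars}
        named = [by_name[n] for n in order if n in by_name]
        rest = [c for c in bars if c.name not in set(order)]
        bars = named + rest
    else:
        bars = sorted(bars, key=lambda c: c.position)
    return bars


def _covariate_strip(build, cov, slots) -> np.ndarray:
    from chmforge.covariates import MISSING_COLOR

    labels = build.matrix.labels(cov.axis)
    strip = np.zeros((len(slots), 3), dtype=np.uint8)
    for i, idx in enumerate(slots):
        if idx is None:
            strip[i] = _parse_hex(GAP_COLOR)
            continue
        v = cov.values.get(labels[idx])
        if cov.kind == "discrete":
            colors = cov.colors or {}
            col = colors.get(v, colors.get("missing", MISSING_COLOR)) if v is not None else colors.get("missing", MISSING_COLOR)
        else:
            col = map_color(cov.colors, v) if cov.colors is not None else MISSING_COLOR
        strip[i] = _parse_hex(col)
    return strip


def _summary_page(build, raster, layout: RenderLayout):
    spec = build.spec
    row_slots = display_slots(build.row_perm, spec.row_gaps)
    col_slots = display_slots(build.col_perm, spec.col_gaps)
    row_bars = _axis_covariates(build, "row")
    col_bars = _axis_covariates(build, "col")

    fig = plt.figure(figsize=layout.page_size)
    fig.suptitle(spec.name, fontsize=12)

    show_row_d = spec.dendrogram_display.get("row", "full") != "none" and build.row_dendrogram
    show_col_d = spec.dendrogram_display.get("col", "full") != "none" and build.col_dendrogram
    left = 0.05 + (layout.dendro_fraction if show_row_d else 0.0)
    top = 0.92 - (layout.dendro_fraction if show_col_d else 0.0)
    bar = layout.covariate_bar_fraction
    left += bar * len(row_bars)
    top -= bar * len(col_bars)
    width = 0.9 - (left - 0.05)
    height = top - 0.08

    ax = fig.add_axes([left, 0.08, width, height])
    ax.imshow(raster, aspect="auto", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])

    if show_col_d:
        axd = fig.add_axes([left, top + bar * len(col_bars), width, layout.dendro_fraction - 0.01])
        _draw_dendrogram(
            axd, build.col_dendrogram, horizontal=True,
            compact=spec.dendrogram_display.get("col") == "compact",
        )
        pos = _slot_positions(col_slots)
        axd.set_xlim(-0.0, len(col_slots))
        # dendrogram x-units are leaf-order ranks; stretch to display slots
        axd.set_xlim(0, build.col_dendrogram.n_leaves)
    if show_row_d:
        axd = fig.add_axes([0.05, 0.08, layout.dendro_fraction - 0.01, height])
        _draw_dendrogram(
            axd, build.row_dendrogram, horizontal=False,
            compact=spec.dendrogram_display.get("row") == "compact",
        )
        axd.set_ylim(build.row_dendrogram.n_leaves, 0)
        axd.invert_xaxis()

    for b, cov in enumerate(col_bars):
        strip = _covariate_strip(build, cov, col_slots)
        axb = fig.add_axes([left, top + b * bar, width, bar * 0.85])
        axb.imshow(strip[np.newaxis, :, :], aspect="auto", interpolation="nearest")
        axb.set_xticks([])
        axb.set_yticks([])
        axb.set_ylabel(_truncate(cov.name, 10), rotation=0, fontsize=5, ha="right", va="center")
    for b, cov in enumerate(row_bars):
        strip = _covariate_strip(build, cov, row_slots)
        axb = fig.add_axes([left - (b + 1) * bar, 0.08, bar * 0.85, height])
        axb.imshow(strip[:, np.newaxis, :], aspect="auto", interpolation="nearest")
        axb.set_xticks([])
        axb.set_yticks([])

    # top-item callouts on the right margin
    if spec.top_items:
        rpos = _slot_positions(row_slots)
        cpos = _slot_positions(col_slots)
        row_idx = {lab: i for i, lab in enumerate(build.matrix.row_labels)}
        col_idx = {lab: j for j, lab in enumerate(build.matrix.col_labels)}
        for item in spec.top_items:
            if item in row_idx and row_idx[item] in rpos:
                y = rpos[row_idx[item]]
                ax.annotate(
                    _truncate(item, layout.label_char_budget),
                    xy=(len(col_slots) - 0.5, y),
                    xytext=(len(col_slots) + max(2, len(col_slots) * 0.02), y),
                    fontsize=5,
                    va="center",
                    arrowprops=dict(arrowstyle="-", linewidth=0.4),
                    annotation_clip=False,
                )
            elif item in col_idx and col_idx[item] in cpos:
                x = cpos[col_idx[item]]
                ax.annotate(
                    _truncate(item, layout.label_char_budget),
                    xy=(x, len(row_slots) - 0.5),
                    xytext=(x, len(row_slots) + max(2, len(row_slots) * 0.05)),
                    fontsize=5,
                    ha="center",
                    rotation=90,
                    arrowprops=dict(arrowstyle="-", linewidth=0.4),
                    annotation_clip=False,
                )
    return fig


def _detail_page(build, layout: RenderLayout):
    spec = build.spec
    n_r, n_c = build.matrix.n_rows, build.matrix.n_cols
    r0, r1 = layout.zoom_rows or (0, min(50, n_r))
    c0, c1 = layout.zoom_cols or (0, min(50, n_c))
    r1, c1 = min(r1, n_r), min(c1, n_c)
    if r0 >= r1 or c0 >= c1:
        raise ValidationError("zoom window lies outside the matrix extent")
    cm = spec.colormap
    rows = build.row_perm[r0:r1]
    cols = build.col_perm[c0:c1]
    sub = np.zeros((len(rows), len(cols), 3), dtype=np.uint8)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            sub[i, j] = _parse_hex(map_color(cm, build.matrix.values[r, c]))
    fig = plt.figure(figsize=layout.page_size)
    fig.suptitle(f"{spec.name} — detail view (rows {r0}–{r1 - 1}, cols {c0}–{c1 - 1})", fontsize=11)
    ax = fig.add_axes([0.12, 0.14, 0.8, 0.74])
    ax.imshow(sub, aspect="auto", interpolation="nearest")
    budget = layout.label_char_budget
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(
        [_truncate(build.matrix.row_labels[r], budget) for r in rows], fontsize=4
    )
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels(
        [_truncate(build.matrix.col_labels[c], budget) for c in cols],
        fontsize=4,
        rotation=90,
    )
    return fig


def _legend_page(build, layout: RenderLayout):
    spec = build.spec
    fig = plt.figure(figsize=layout.page_size)
    fig.suptitle("Legends and metadata", fontsize=12)

    # colormap scale
    cm = spec.colormap
    ax = fig.add_axes([0.08, 0.78, 0.4, 0.06])
    lo, hi = cm.breakpoints[0], cm.breakpoints[-1]
    xs = np.linspace(lo, hi, 256)
    strip = np.array([[_parse_hex(map_color(cm, x)) for x in xs]], dtype=np.uint8)
    ax.imshow(strip, aspect="auto", interpolation="nearest", extent=[lo, hi, 0, 1])
    ax.set_yticks([])
    ax.set_xticks(cm.breakpoints)
    ax.tick_params(labelsize=6)
    ax.set_title("Body colors", fontsize=8, loc="left")

    # covariate legends
    y = 0.70
    for cov in build.covariates:
        ax = fig.add_axes([0.08, y, 0.4, 0.05])
        ax.set_axis_off()
        ax.set_title(f"{cov.name} ({cov.axis}, {cov.kind})", fontsize=7, loc="left")
        if cov.kind == "discrete":
            cats = cov.categories()
            for i, cat in enumerate(cats[:12]):
                color = (cov.colors or {}).get(cat, "#CCCCCC")
                ax.add_patch(Rectangle((i * 0.08, 0.0), 0.03, 0.8, facecolor=color, edgecolor="black", linewidth=0.3))
                ax.text(i * 0.08 + 0.035, 0.4, _truncate(str(cat), 10), fontsize=5, va="center")
            ax.set_xlim(0, 1)
        else:
            ccm = cov.colors
            if ccm is not None:
                xs = np.linspace(ccm.breakpoints[0], ccm.breakpoints[-1], 128)
                strip = np.array([[_parse_hex(map_color(ccm, x)) for x in xs]], dtype=np.uint8)
                ax.set_axis_on()
                ax.imshow(strip, aspect="auto", extent=[xs[0], xs[-1], 0, 1])
                ax.set_yticks([])
                ax.tick_params(labelsize=5)
        y -= 0.09

    # metadata block
    meta = [
        f"Name: {spec.name}",
        f"Description: {spec.description or '—'}",
        f"Matrix: {build.matrix.n_rows} rows × {build.matrix.n_cols} columns",
        f"Row order: {spec.row_order.to_dict()}",
        f"Column order: {spec.col_order.to_dict()}",
        f"Row label type: {spec.row_label_type};  column label type: {spec.col_label_type}",
        f"Gaps: rows {spec.row_gaps or '—'}, columns {spec.col_gaps or '—'}",
        f"Top items: {', '.join(spec.top_items) or '—'}",
        f"Creation log: {len(build.log.events)} recorded events",
    ]
    fig.text(0.55, 0.85, "\n".join(meta), fontsize=7, va="top", family="monospace")
    return fig
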