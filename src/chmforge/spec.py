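"""The complete formatting option set for a heat map.

:class:`HeatMapSpec` is the in-memory twin of the properties document
serialized into the archive: body colormap and breakpoints, axis
ordering configs, label link-out types, gaps, top items, covariate bar
order, and dendrogram display flags.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from chmforge.cluster import OrderSpec
from chmforge.errors import ValidationError

_HEX_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")


def _parse_hex(c: str) -> tuple[int, int, int]:
    if not _HEX_RE.match(c):
        raise ValidationError(f"invalid hex color {c!r}")
    return int(c[1:3], 16), int(c[3:5], 16), int(c[5:7], 16)


def _to_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


@dataclass
class ColorMap:
    """Piecewise-linear value→color mapping over strictly increasing
    breakpoints, with a dedicated color for missing cells."""

    breakpoints: list[float]
    colors: list[str]
    missing_color: str = "#FFFFFF"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.breakpoints) != len(self.colors) or len(self.breakpoints) < 2:
            raise ValidationError(
                "colormap needs one color per breakpoint and at least 2 breakpoints"
            )
        bp = [float(b) for b in self.breakpoints]
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValidationError(f"breakpoints must be strictly increasing, got {bp}")
        for c in list(self.colors) + [self.missing_color]:
            _parse_hex(c)
        self.breakpoints = bp

    def to_dict(self) -> dict:
        return {
            "breakpoints": list(self.breakpoints),
            "colors": list(self.colors),
            "missing_color": self.missing_color,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColorMap":
        return cls(
            breakpoints=list(d["breakpoints"]),
            colors=list(d["colors"]),
            missing_color=d.get("missing_color", "#FFFFFF"),
        )


def map_color(cm: ColorMap, v) -> str:
    """Color for one value: missing → missing color, out-of-range values
    clamp to the end colors, in-range values interpolate channel-wise
    linearly between the flanking breakpoints."""
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return cm.missing_color
    v = float(v)
    bp = cm.breakpoints
    if v <= bp[0]:
        return cm.colors[0]
    if v >= bp[-1]:
        return cm.colors[-1]
    for i in range(len(bp) - 1):
        if bp[i] <= v <= bp[i + 1]:
            frac = (v - bp[i]) / (bp[i + 1] - bp[i])
            c0 = _parse_hex(cm.colors[i])
            c1 = _parse_hex(cm.colors[i + 1])
            rgb = tuple(
                int(a + (b - a) * frac + 0.5) for a, b in zip(c0, c1)
            )
            return _to_hex(rgb)
    raise AssertionError("unreachable: breakpoints cover the clamped range")


def default_colormap(values: np.ndarray) -> ColorMap:
    """Blue–white–red over the 5th percentile, median and 95th percentile
    of the non-missing values; degenerate spreads are widened so the
    breakpoints stay strictly increasing."""
    finite = values[~np.isnan(values)] if values.size else np.array([])
    if finite.size == 0:
        lo, mid, hi = -1.0, 0.0, 1.0
    else:
        lo, mid, hi = (float(np.percentile(finite, q)) for q in (5, 50, 95))
    if not lo < mid:
        mid = lo + max(abs(lo), 1.0) * 1e-6
    if not mid < hi:
        hi = mid + max(abs(mid), 1.0) * 1e-6
    return ColorMap(
        breakpoints=[lo, mid, hi],
        colors=["#0000FF", "#FFFFFF", "#FF0000"],
        missing_color="#FFFFFF",
    )


def insert_gaps(order: list[int], gaps: list[int]) -> list[list[int]]:
    """Partition a display order into contiguous blocks at the gap
    positions (gap after display index ``g`` means between items g-1 and
    g... positions are counted 1..n-1, "after the g-th displayed item").

    Data values and ordering are untouched; only the layout blocks are
    produced.
    """
    n = len(order)
    blocks: list[list[int]] = []
    prev = 0
    for g in sorted(set(int(g) for g in gaps)):
        if not (1 <= g <= n - 1):
            raise ValidationError(f"gap position {g} out of range 1..{n - 1}")
        blocks.append(list(order[prev:g]))
        prev = g
    blocks.append(list(order[prev:]))
    return blocks


@dataclass
class HeatMapSpec:
    """Every formatting option of a build, in one serializable object."""

    name: str = "Heat Map"
    description: str = ""
    colormap: ColorMap | None = None
    row_order: OrderSpec = field(default_factory=OrderSpec)
    col_order: OrderSpec = field(default_factory=OrderSpec)
    row_label_type: str = "text"
    col_label_type: str = "text"
    row_gaps: list[int] = field(default_factory=list)
    col_gaps: list[int] = field(default_factory=list)
    top_items: list[str] = field(default_factory=list)
    covariate_order: dict = field(default_factory=lambda: {"row": [], "col": []})
    dendrogram_display: dict = field(
        default_factory=lambda: {"row": "full", "col": "full"}
    )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "colormap": self.colormap.to_dict() if self.colormap else None,
            "row_order": self.row_order.to_dict(),
            "col_order": self.col_order.to_dict(),
            "row_label_type": self.row_label_type,
            "col_label_type": self.col_label_type,
            "row_gaps": [int(g) for g in self.row_gaps],
            "col_gaps": [int(g) for g in self.col_gaps],
            "top_items": list(self.top_items),
            "covariate_order": {
                "row": list(self.covariate_order.get("row", [])),
                "col": list(self.covariate_order.get("col", [])),
            },
            "dendrogram_display": dict(self.dendrogram_display),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HeatMapSpec":
        return cls(
            name=d.get("name", "Heat Map"),
            description=d.get("description", ""),
            colormap=ColorMap.from_dict(d["colormap"]) if d.get("colormap") else None,
            row_order=OrderSpec.from_dict(d.get("row_order", {})),
            col_order=OrderSpec.from_dict(d.get("col_order", {})),
            row_label_type=d.get("row_label_type", "text"),
            col_label_type=d.get("col_label_type", "text"),
            row_gaps=list(d.get("row_gaps", [])),
            col_gaps=list(d.get("col_gaps", [])),
            top_items=list(d.get("top_items", [])),
            covariate_order=d.get("covariate_order", {"row": [], "col": []}),
            dendrogram_display=d.get(
                "dendrogram_display", {"row": "full", "col": "full"}
            ),
        )


def validate_spec(spec: HeatMapSpec, session, covariates: list) -> list[str]:
    """Cross-check a spec against the working matrix and covariates.

    Returns advisory warnings (dropping unknown top items in place);
    raises :class:`ValidationError` on hard inconsistencies such as
    non-increasing breakpoints or out-of-range gaps.
    """
    warnings_out: list[str] = []
    m = session.working
    if spec.colormap is not None:
        spec.colormap.validate()
    for axis, gaps, n in (("row", spec.row_gaps, m.n_rows), ("col", spec.col_gaps, m.n_cols)):
        for g in gaps:
            if not (1 <= int(g) <= n - 1):
                raise ValidationError(
                    f"{axis} gap position {g} out of range 1..{n - 1}"
                )
    if spec.top_items:
        known = set(m.row_labels) | set(m.col_labels)
        kept = []
        for item in spec.top_items:
            if item in known:
                kept.append(item)
            else:
                warnings_out.append(f"top item {item!r} not among axis labels; dropped")
        spec.top_items = kept
    for d in spec.dendrogram_display.values():
        if d not in ("none", "compact", "full"):
            raise ValidationError(f"dendrogram display must be none|compact|full, got {d!r}")
    names = {(c.axis, c.name) for c in covariates}
    for axis in ("row", "col"):
        for nm in spec.covariate_order.get(axis, []):
            if (axis, nm) not in names:
                warnings_out.append(
                    f"covariate order names unknown {axis} covariate {nm!r}"
                )
    return warnings_out
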