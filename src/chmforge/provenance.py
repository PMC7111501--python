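"""Creation log and the high-level Builder that drives a whole build.

Every option chosen through :class:`Builder` is recorded as one
:class:`LogEvent`.  Replaying the log against the original input files
reproduces an equal build state, and — because archive writing is
deterministic — a byte-identical ``.ngchm`` archive.  Timestamps are
carried for human readers but excluded from the canonical serialization
used inside the archive and for replay comparison.
"""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field

from chmforge.cluster import OrderSpec, check_size, cut_top_branches, order_axis
from chmforge.covariates import Covariate, Palette, default_colors, parse_covariate, reorder_bars
from chmforge.errors import ValidationError
from chmforge.matrix import RegionSpec
from chmforge.matrix_io import parse_matrix
from chmforge.spec import ColorMap, HeatMapSpec, default_colormap, validate_spec
from chmforge.transforms import MatrixSession, TransformStep

STEPS = ("select_matrix", "transform", "cluster", "covariate", "format", "output")

_LOG_HEADER = "# chmforge creation log v1"


@dataclass(frozen=True)
class LogEvent:
    """One option event: which build step, what action, with which
    parameters."""

    step: str
    action: str
    params: dict = field(default_factory=dict)
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if self.step not in STEPS:
            raise ValidationError(f"unknown log step {self.step!r}")

    def serialize(self, with_timestamp: bool = True) -> str:
        parts = ";".join(f"{k}={json.dumps(self.params[k])}" for k in sorted(self.params))
        line = f"{self.step}\t{self.action}\t{parts}"
        if with_timestamp and self.timestamp:
            line += f"\t{self.timestamp}"
        return line

    @classmethod
    def deserialize(cls, line: str) -> "LogEvent":
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"malformed log line {line!r}")
        step, action, raw = fields[0], fields[1], fields[2]
        ts = fields[3] if len(fields) > 3 else None
        params = {}
        if raw.strip():
            for kv in raw.split(";"):
                k, _, v = kv.partition("=")
                params[k] = json.loads(v)
        return cls(step, action, params, ts)

    def same_option(self, other: "LogEvent") -> bool:
        """Equality ignoring the timestamp."""
        return (
            self.step == other.step
            and self.action == other.action
            and self.params == other.params
        )


@dataclass
class CreationLog:
    events: list[LogEvent] = field(default_factory=list)

    def record(self, event: LogEvent) -> "CreationLog":
        self.events.append(event)
        return self

    def serialize(self, with_timestamps: bool = True) -> str:
        lines = [_LOG_HEADER]
        lines += [e.serialize(with_timestamps) for e in self.events]
        return "\n".join(lines) + "\n"

    @classmethod
    def deserialize(cls, text: str) -> "CreationLog":
        events = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            events.append(LogEvent.deserialize(line))
        return cls(events)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.serialize())

    @classmethod
    def load(cls, path: str) -> "CreationLog":
        with open(path, encoding="utf-8") as fh:
            return cls.deserialize(fh.read())

    def same_options(self, other: "CreationLog") -> bool:
        return len(self.events) == len(other.events) and all(
            a.same_option(b) for a, b in zip(self.events, other.events)
        )


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


class Builder:
    """Step-by-step heat-map construction with full provenance.

    Public methods mirror the builder's pages (select matrix, transform,
    cluster, covariate, format, output); each both updates the build
    state and appends the corresponding event to the creation log, so
    the log is always sufficient to recreate the current state.
    """

    def __init__(
        self,
        name: str = "Heat Map",
        description: str = "",
        size_limit: int = 5000,
        palette: Palette | None = None,
    ):
        self.size_limit = size_limit
        self.palette = palette
        self.log = CreationLog()
        self.session: MatrixSession | None = None
        self.covariates: list[Covariate] = []
        self.spec = HeatMapSpec()
        self._top_branch_requests: list[tuple[str, int]] = []
        self._covariate_dir: str | None = None
        self._covariate_files: dict[str, str] = {}
        # name/description go through the log so replay reproduces them
        if name != self.spec.name or description:
            self.set_format(name=name, description=description)

    # -- event plumbing ----------------------------------------------------

    def _do(self, step: str, action: str, params: dict) -> None:
        event = LogEvent(step, action, params, timestamp=_now())
        self.apply_event(event, record=True)

    def apply_event(self, event: LogEvent, record: bool = True) -> None:
        """Apply one log event to the build state (the single dispatch
        point used by both live building and replay)."""
        handler = getattr(self, f"_ev_{event.step}", None)
        if handler is None:
            raise ValidationError(f"unhandled log step {event.step!r}")
        handler(event.action, dict(event.params))
        if record:
            self.log.record(event)

    def _require_session(self) -> MatrixSession:
        if self.session is None:
            raise ValidationError("no matrix imported yet")
        return self.session

    # -- select matrix -----------------------------------------------------

    def import_matrix(self, path: str, region: RegionSpec | None = None) -> None:
        params: dict = {"file": os.path.basename(path)}
        if region is not None:
            params["region"] = [
                region.label_row_index,
                region.label_col_index,
                region.data_origin[0],
                region.data_origin[1],
            ]
        self._input_path = path
        self._do("select_matrix", "import", params)

    def _ev_select_matrix(self, action: str, params: dict) -> None:
        if action != "import":
            raise ValidationError(f"unknown select_matrix action {action!r}")
        path = getattr(self, "_input_path", None)
        if path is None or os.path.basename(path) != params["file"]:
            raise ValidationError(
                f"replay requires the original input file {params['file']!r}"
            )
        region = None
        if "region" in params:
            lr, lc, r0, c0 = params["region"]
            region = RegionSpec(lr, lc, (r0, c0))
        m = parse_matrix(path, region)
        self.session = MatrixSession(original=m)

    # -- transforms ----------------------------------------------------------

    def transform(self, action: str, **params) -> None:
        self._do("transform", action, params)

    def undo_to(self, k: int) -> None:
        self._do("transform", "undo_to", {"k": int(k)})

    def _ev_transform(self, action: str, params: dict) -> None:
        s = self._require_session()
        if action == "undo_to":
            s.undo_to(int(params["k"]))
        else:
            s.apply_step(TransformStep(action, params))

    # -- clustering ----------------------------------------------------------

    def set_order(self, axis: str, spec: OrderSpec) -> None:
        self._do("cluster", f"order_{axis}", spec.to_dict())

    def add_top_branch_covariate(self, axis: str, k: int) -> None:
        self._do("cluster", "top_branches", {"axis": axis, "k": int(k)})

    def _ev_cluster(self, action: str, params: dict) -> None:
        if action in ("order_row", "order_col"):
            axis = action.removeprefix("order_")
            spec = OrderSpec.from_dict(params)
            if axis == "row":
                self.spec.row_order = spec
            else:
                self.spec.col_order = spec
        elif action == "top_branches":
            self._top_branch_requests.append((params["axis"], int(params["k"])))
        else:
            raise ValidationError(f"unknown cluster action {action!r}")

    # -- covariates ----------------------------------------------------------

    def add_covariate(
        self, path: str, axis: str, kind: str, name: str | None = None
    ) -> None:
        if name is None:
            name = os.path.splitext(os.path.basename(path))[0]
        self._covariate_files[os.path.basename(path)] = path
        self._do(
            "covariate",
            "add_file",
            {"file": os.path.basename(path), "axis": axis, "kind": kind, "name": name},
        )

    def reorder_covariates(self, axis: str, order: list[int]) -> None:
        self._do("covariate", "reorder", {"axis": axis, "order": [int(i) for i in order]})

    def set_covariate_colors(self, name: str, axis: str, colors: dict) -> None:
        self._do(
            "covariate", "set_colors", {"name": name, "axis": axis, "colors": colors}
        )

    def _ev_covariate(self, action: str, params: dict) -> None:
        s = self._require_session()
        if action == "add_file":
            fname = params["file"]
            path = self._covariate_files.get(fname)
            if path is None and self._covariate_dir is not None:
                cand = os.path.join(self._covariate_dir, fname)
                path = cand if os.path.exists(cand) else None
            if path is None or not os.path.exists(path):
                raise ValidationError(
                    f"creation log references covariate file {fname!r}, "
                    f"which was not provided"
                )
            cov = parse_covariate(
                path,
                params["axis"],
                params["kind"],
                s.working.labels(params["axis"]),
                name=params["name"],
            )
            cov.position = sum(1 for c in self.covariates if c.axis == cov.axis)
            self.covariates.append(cov)
        elif action == "reorder":
            axis = params["axis"]
            same_axis = [c for c in self.covariates if c.axis == axis]
            reordered = reorder_bars(same_axis, [int(i) for i in params["order"]])
            others = [c for c in self.covariates if c.axis != axis]
            self.covariates = others + reordered
        elif action == "set_colors":
            for c in self.covariates:
                if c.name == params["name"] and c.axis == params["axis"]:
                    colors = params["colors"]
                    if isinstance(colors, dict) and "breakpoints" in colors:
                        c.colors = ColorMap.from_dict(colors)
                    else:
                        c.colors = colors
                    return
            raise ValidationError(f"no covariate named {params['name']!r}")
        else:
            raise ValidationError(f"unknown covariate action {action!r}")

    # -- format --------------------------------------------------------------

    def set_format(self, **options) -> None:
        """Record and apply any subset of the formatting options:
        ``name``, ``description``, ``colormap`` (dict), ``row_label_type``,
        ``col_label_type``, ``row_gaps``, ``col_gaps``, ``top_items``,
        ``dendrogram_display`` (dict axis→mode), ``covariate_order``."""
        self._do("format", "set", options)

    def _ev_format(self, action: str, params: dict) -> None:
        if action != "set":
            raise ValidationError(f"unknown format action {action!r}")
        known = {
            "name",
            "description",
            "colormap",
            "row_label_type",
            "col_label_type",
            "row_gaps",
            "col_gaps",
            "top_items",
            "dendrogram_display",
            "covariate_order",
        }
        for key, val in params.items():
            if key not in known:
                raise ValidationError(f"unknown format option {key!r}")
            if key == "colormap":
                self.spec.colormap = ColorMap.from_dict(val)
            elif key == "dendrogram_display":
                self.spec.dendrogram_display.update(val)
            elif key == "covariate_order":
                self.spec.covariate_order.update(
                    {k: list(v) for k, v in val.items()}
                )
            else:
                setattr(self.spec, key, val)

    def _ev_output(self, action: str, params: dict) -> None:
        pass  # marker event: outputs are derived, not state

    # -- build ---------------------------------------------------------------

    def build(self):
        """Assemble the complete build state: size gate, axis ordering,
        derived covariates, default colors, validation."""
        from chmforge.archive import CHMBuild

        s = self._require_session()
        check_size(s.working, self.size_limit)
        row_perm, row_dend = order_axis(s.working, "row", self.spec.row_order)
        col_perm, col_dend = order_axis(s.working, "col", self.spec.col_order)
        covariates = [
            Covariate(
                name=c.name,
                axis=c.axis,
                kind=c.kind,
                values=dict(c.values),
                colors=c.colors,
                position=c.position,
            )
            for c in self.covariates
        ]
        for axis, k in self._top_branch_requests:
            dend = row_dend if axis == "row" else col_dend
            if dend is None:
                raise ValidationError(
                    f"top-branch covariate requires the {axis} axis to be clustered"
                )
            cov = cut_top_branches(dend, k, labels=s.working.labels(axis), axis=axis)
            cov.position = sum(1 for c in covariates if c.axis == axis)
            covariates.append(cov)
        for c in covariates:
            if c.colors is None:
                default_colors(c, self.palette)
        spec = HeatMapSpec.from_dict(self.spec.to_dict())  # defensive copy
        if spec.colormap is None:
            spec.colormap = default_colormap(s.working.values)
        warnings_out = validate_spec(spec, s, covariates)
        return CHMBuild(
            matrix=s.working.copy(),
            spec=spec,
            row_perm=row_perm,
            col_perm=col_perm,
            row_dendrogram=row_dend,
            col_dendrogram=col_dend,
            covariates=covariates,
            log=CreationLog(list(self.log.events)),
            warnings=warnings_out,
        )

    def write(self, out_dir: str, basename: str = "map", pdf: bool = True) -> dict:
        """Run the output step: write ``.ngchm`` archive, PDF and the
        creation log into ``out_dir``; returns the paths written."""
        from chmforge.archive import write_ngchm
        from chmforge.render import RenderLayout, render_pdf

        self._do("output", "build", {"formats": ["ngchm", "pdf", "log"] if pdf else ["ngchm", "log"]})
        build = self.build()
        os.makedirs(out_dir, exist_ok=True)
        paths = {"ngchm": os.path.join(out_dir, f"{basename}.ngchm")}
        write_ngchm(build, paths["ngchm"])
        if pdf:
            paths["pdf"] = os.path.join(out_dir, f"{basename}.pdf")
            render_pdf(build, RenderLayout(), paths["pdf"])
        paths["log"] = os.path.join(out_dir, f"{basename}_creation_log.txt")
        self.log.save(paths["log"])
        return paths


def replay(
    original_input: str,
    log: CreationLog,
    covariate_files: dict[str, str] | None = None,
    size_limit: int = 5000,
    palette: Palette | None = None,
):
    """Rebuild the complete build state from the original input + log.

    ``covariate_files`` maps the basenames recorded in the log to their
    paths; basenames are also searched next to the input file.  Returns
    the :class:`CHMBuild`; writing it yields a byte-identical archive.
    """
    b = Builder(size_limit=size_limit, palette=palette)
    b._input_path = original_input
    b._covariate_dir = os.path.dirname(os.path.abspath(original_input))
    b._covariate_files = dict(covariate_files or {})
    for event in log.events:
        b.apply_event(event, record=True)
    return b.build()
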