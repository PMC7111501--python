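"""NG-CHM archive reader/writer.

An ``.ngchm`` file is a zip archive around a ``heatmapProperties.json``
options document.  This module defines its own versioned schema
(``schema_version``): the properties document carries the full
:class:`HeatMapSpec`, axis permutations, dendrogram trees, covariate
definitions and a file manifest; sibling entries hold the matrix payload
(tab-delimited, display order), per-axis Newick dendrograms, per-bar
covariate tables, and the canonical creation log.  Writing is
byte-deterministic: entries are emitted in sorted name order with fixed
epoch timestamps, so equal builds produce equal archives.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from chmforge.cluster import Dendrogram
from chmforge.covariates import Covariate
from chmforge.errors import FormatError, ValidationError
from chmforge.matrix import LabeledMatrix
from chmforge.matrix_io import format_number, matrix_from_text, matrix_to_text
from chmforge.provenance import CreationLog
from chmforge.spec import HeatMapSpec

SCHEMA_VERSION = 1
PROPERTIES_NAME = "heatmapProperties.json"
MATRIX_NAME = "matrix.tsv"
LOG_NAME = "creation_log.txt"
MANIFEST_NAME = "manifest.json"
_ZIP_EPOCH = (1980, 1, 1, 0, 0, 0)


@dataclass
class CHMBuild:
    """The complete state of a finished heat-map build."""

    matrix: LabeledMatrix  # working matrix, original orientation
    spec: HeatMapSpec
    row_perm: list[int]
    col_perm: list[int]
    row_dendrogram: Dendrogram | None = None
    col_dendrogram: Dendrogram | None = None
    covariates: list[Covariate] = field(default_factory=list)
    log: CreationLog = field(default_factory=CreationLog)
    warnings: list[str] = field(default_factory=list)
    extra_entries: dict[str, bytes] = field(default_factory=dict)

    def display_matrix(self) -> LabeledMatrix:
        """The working matrix permuted into display order."""
        rp, cp = self.row_perm, self.col_perm
        return LabeledMatrix(
            [self.matrix.row_labels[i] for i in rp],
            [self.matrix.col_labels[j] for j in cp],
            self.matrix.values[np.ix_(rp, cp)],
            n_invalid=self.matrix.n_invalid,
        )

    def equals(self, other: "CHMBuild") -> bool:
        """State equality: matrix cells, orders, covariates, spec, log
        options (timestamps ignored)."""
        if not self.matrix.equals(other.matrix):
            return False
        if self.row_perm != other.row_perm or self.col_perm != other.col_perm:
            return False
        if self.spec.to_dict() != other.spec.to_dict():
            return False
        if len(self.covariates) != len(other.covariates):
            return False
        for a, b in zip(self.covariates, other.covariates):
            if _cov_key(a) != _cov_key(b):
                return False
        for a, b in (
            (self.row_dendrogram, other.row_dendrogram),
            (self.col_dendrogram, other.col_dendrogram),
        ):
            if (a is None) != (b is None):
                return False
            if a is not None and a.to_dict() != b.to_dict():
                return False
        return self.log.same_options(other.log)


def _cov_key(c: Covariate) -> tuple:
    return (c.name, c.axis, c.kind, json.dumps(c.to_dict(), sort_keys=True))


def _covariate_entry_name(c: Covariate, index: int) -> str:
    safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in c.name)
    return f"covariates/{index:02d}_{c.axis}_{safe}.tsv"


def _covariate_payload(c: Covariate, labels: list[str]) -> str:
    lines = []
    for lab in labels:
        v = c.values.get(lab)
        if c.kind == "continuous":
            v = format_number(float(v)) if v is not None and not (
                isinstance(v, float) and np.isnan(v)
            ) else "NA"
        else:
            v = v if v is not None else "NA"
        lines.append(f"{lab}\t{v}")
    return "\n".join(lines) + "\n"


def build_entries(build: CHMBuild) -> dict[str, bytes]:
    """All archive members (name → bytes) except the manifest."""
    entries: dict[str, bytes] = {}
    display = build.display_matrix()
    entries[MATRIX_NAME] = matrix_to_text(display).encode("utf-8")
    entries[LOG_NAME] = build.log.serialize(with_timestamps=False).encode("utf-8")

    dendro_files = {}
    for axis, dend in (("row", build.row_dendrogram), ("col", build.col_dendrogram)):
        if dend is not None:
            name = f"dendrogram_{axis}.newick"
            labels = build.matrix.labels(axis)
            entries[name] = (dend.to_newick(labels) + "\n").encode("utf-8")
            dendro_files[axis] = name

    cov_docs = []
    for i, c in enumerate(build.covariates):
        entry = _covariate_entry_name(c, i)
        entries[entry] = _covariate_payload(c, build.matrix.labels(c.axis)).encode("utf-8")
        doc = c.to_dict()
        doc["file"] = entry
        cov_docs.append(doc)

    props = {
        "schema_version": SCHEMA_VERSION,
        "generator": "chmforge",
        "spec": build.spec.to_dict(),
        "row_perm": [int(i) for i in build.row_perm],
        "col_perm": [int(j) for j in build.col_perm],
        "row_dendrogram": build.row_dendrogram.to_dict() if build.row_dendrogram else None,
        "col_dendrogram": build.col_dendrogram.to_dict() if build.col_dendrogram else None,
        "dendrogram_files": dendro_files,
        "covariates": cov_docs,
        "matrix_file": MATRIX_NAME,
        "log_file": LOG_NAME,
        "n_invalid": int(build.matrix.n_invalid),
    }
    entries[PROPERTIES_NAME] = (
        json.dumps(props, indent=2, sort_keys=True) + "\n"
    ).encode("utf-8")
    for name, data in build.extra_entries.items():
        entries.setdefault(name, data)
    return entries


def write_ngchm(build: CHMBuild, path: str) -> None:
    """Write the build as a deterministic ``.ngchm`` zip archive."""
    entries = build_entries(build)
    manifest = {
        "entries": {
            name: hashlib.sha256(data).hexdigest() for name, data in sorted(entries.items())
        }
    }
    entries[MANIFEST_NAME] = (
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    ).encode("utf-8")
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(entries):
            zi = zipfile.ZipInfo(name, date_time=_ZIP_EPOCH)
            zi.compress_type = zipfile.ZIP_DEFLATED
            zi.external_attr = 0o644 << 16
            zf.writestr(zi, entries[name])
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def _require(props: dict, key: str):
    if key not in props:
        raise ValidationError(f"properties document missing required key {key!r}")
    return props[key]


def read_ngchm(path: str) -> CHMBuild:
    """Read an archive back into a :class:`CHMBuild`.

    Unknown extra entries are preserved opaquely and re-emitted on the
    next write.
    """
    try:
        zf = zipfile.ZipFile(path)
        names = zf.namelist()
    except (zipfile.BadZipFile, OSError) as exc:
        raise FormatError(f"{path!r} is not a readable zip archive: {exc}") from exc
    with zf:
        if PROPERTIES_NAME not in names:
            raise FormatError(
                f"{path!r} has no {PROPERTIES_NAME}; not an NG-CHM archive"
            )
        try:
            props = json.loads(zf.read(PROPERTIES_NAME).decode("utf-8"))
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed {PROPERTIES_NAME}: {exc}") from exc
        version = _require(props, "schema_version")
        if version != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
            )
        spec = HeatMapSpec.from_dict(_require(props, "spec"))
        row_perm = [int(i) for i in _require(props, "row_perm")]
        col_perm = [int(j) for j in _require(props, "col_perm")]
        matrix_file = _require(props, "matrix_file")
        if matrix_file not in names:
            raise ValidationError(f"manifest names missing matrix payload {matrix_file!r}")
        display = matrix_from_text(zf.read(matrix_file).decode("utf-8"))
        display.n_invalid = int(props.get("n_invalid", 0))
        matrix = _unpermute(display, row_perm, col_perm)

        dendros = {}
        for axis in ("row", "col"):
            d = props.get(f"{axis}_dendrogram")
            dendros[axis] = Dendrogram.from_dict(d) if d else None

        covariates = []
        cov_files = set()
        for doc in props.get("covariates", []):
            cov_files.add(doc.get("file"))
            doc = {k: v for k, v in doc.items() if k != "file"}
            covariates.append(Covariate.from_dict(doc))

        log_file = props.get("log_file", LOG_NAME)
        log = (
            CreationLog.deserialize(zf.read(log_file).decode("utf-8"))
            if log_file in names
            else CreationLog()
        )

        known = (
            {PROPERTIES_NAME, MANIFEST_NAME, matrix_file, log_file}
            | set(props.get("dendrogram_files", {}).values())
            | cov_files
        )
        extras = {n: zf.read(n) for n in names if n not in known}

    return CHMBuild(
        matrix=matrix,
        spec=spec,
        row_perm=row_perm,
        col_perm=col_perm,
        row_dendrogram=dendros["row"],
        col_dendrogram=dendros["col"],
        covariates=covariates,
        log=log,
        extra_entries=extras,
    )


def _unpermute(display: LabeledMatrix, row_perm: list[int], col_perm: list[int]) -> LabeledMatrix:
    n, m = display.n_rows, display.n_cols
    if sorted(row_perm) != list(range(n)) or sorted(col_perm) != list(range(m)):
        raise ValidationError("row_perm/col_perm are not permutations of the payload shape")
    row_labels = [""] * n
    col_labels = [""] * m
    values = np.empty((n, m))
    for i, src in enumerate(row_perm):
        row_labels[src] = display.row_labels[i]
    for j, src in enumerate(col_perm):
        col_labels[src] = display.col_labels[j]
    inv_r = np.argsort(np.asarray(row_perm))
    inv_c = np.argsort(np.asarray(col_perm))
    values = display.values[np.ix_(inv_r, inv_c)]
    return LabeledMatrix(row_labels, col_labels, values, n_invalid=display.n_invalid)
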