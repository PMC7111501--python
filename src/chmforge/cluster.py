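"""Axis ordering: agglomerative hierarchical clustering, original order,
or seeded random order.

Distances support missing values through pairwise-complete rescaling:
for two vectors sharing ``s`` of ``t`` positions, the distance summed
over shared positions is scaled by ``t / s`` (inside the square root for
Euclidean), the convention used by ``dist``-style implementations.

Agglomeration itself runs through :func:`scipy.cluster.hierarchy.linkage`
on the precomputed condensed distance matrix; Ward therefore follows
ward.D2 semantics (squared-distance Lance-Williams update on the given
distances).  Leaf ordering is this module's own deterministic
convention: at every merge the subtree containing the smallest original
index is placed on the left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist, squareform

from chmforge.errors import SizeLimitError, ValidationError
from chmforge.matrix import LabeledMatrix, _check_axis

DEFAULT_SIZE_LIMIT = 5000

LINKAGES = ("ward", "complete", "average", "single")
METRICS = ("euclidean", "manhattan", "correlation")


@dataclass(frozen=True)
class OrderSpec:
    """How to order one axis: cluster it, keep it, or shuffle it."""

    mode: str = "original"  # cluster | original | random
    linkage: str | None = None
    distance: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cluster", "original", "random"):
            raise ValidationError(f"unknown order mode {self.mode!r}")
        if self.mode == "cluster":
            if self.linkage not in LINKAGES:
                raise ValidationError(
                    f"linkage must be one of {LINKAGES}, got {self.linkage!r}"
                )
            if self.distance not in METRICS:
                raise ValidationError(
                    f"distance must be one of {METRICS}, got {self.distance!r}"
                )
        if self.mode == "random" and self.seed is None:
            raise ValidationError("random order requires a seed")

    def to_dict(self) -> dict:
        d = {"mode": self.mode}
        if self.mode == "cluster":
            d.update(linkage=self.linkage, distance=self.distance)
        if self.mode == "random":
            d["seed"] = int(self.seed)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OrderSpec":
        return cls(
            mode=d.get("mode", "original"),
            linkage=d.get("linkage"),
            distance=d.get("distance"),
            seed=d.get("seed"),
        )


@dataclass
class Dendrogram:
    """Merge tree in R ``hclust`` convention plus a leaf order.

    ``merges`` holds n-1 pairs; a negative entry ``-i`` is leaf ``i-1``
    (1-based negation), a positive entry ``k`` refers to merge ``k``
    (1-based).  ``heights`` are the merge distances.  ``leaf_order`` is
    the left-to-right permutation of 0..n-1 used for display.
    """

    merges: list[tuple[int, int]]
    heights: list[float]
    leaf_order: list[int]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    def to_dict(self) -> dict:
        return {
            "merges": [list(p) for p in self.merges],
            "heights": [float(h) for h in self.heights],
            "leaf_order": [int(i) for i in self.leaf_order],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Dendrogram":
        return cls(
            merges=[tuple(p) for p in d["merges"]],
            heights=list(d["heights"]),
            leaf_order=list(d["leaf_order"]),
        )

    def to_newick(self, labels: list[str] | None = None) -> str:
        """Newick text with branch lengths = parent height − child height."""
        n = self.n_leaves
        if labels is None:
            labels = [str(i) for i in range(n)]
        if n == 1:
            return f"{_newick_escape(labels[0])}:0;"

        def node_height(ref: int) -> float:
            return 0.0 if ref < 0 else self.heights[ref - 1]

        def render(ref: int, parent_h: float) -> str:
            if ref < 0:
                leaf = -ref - 1
                return f"{_newick_escape(labels[leaf])}:{parent_h - 0.0:.10g}"
            h = self.heights[ref - 1]
            a, b = self.merges[ref - 1]
            inner = f"({render(a, h)},{render(b, h)})"
            return f"{inner}:{parent_h - h:.10g}"

        top = len(self.merges)  # last merge is the root
        h = self.heights[top - 1]
        a, b = self.merges[top - 1]
        return f"({render(a, h)},{render(b, h)});"


def _newick_escape(name: str) -> str:
    if any(c in name for c in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def check_size(m: LabeledMatrix, limit: int = DEFAULT_SIZE_LIMIT) -> None:
    """Raise :class:`SizeLimitError` unless rows + columns <= limit."""
    if m.n_rows + m.n_cols > limit:
        raise SizeLimitError(m.n_rows, m.n_cols, limit)


# ---------------------------------------------------------------------------
# distances


def distance_matrix(m: LabeledMatrix, axis: str, metric: str) -> np.ndarray:
    """Square symmetric distance matrix among the vectors on one axis.

    Missing cells are handled pairwise-complete with total/shared
    rescaling; correlation distance is 1 − Pearson r.
    """
    _check_axis(axis)
    if metric not in METRICS:
        raise ValidationError(f"distance must be one of {METRICS}, got {metric!r}")
    vecs = m.values if axis == "row" else m.values.T
    n, t = vecs.shape
    if n < 2:
        raise ValidationError("distance matrix needs at least 2 vectors")
    mask = ~np.isnan(vecs)
    shared = mask.astype(np.int64) @ mask.T.astype(np.int64)
    off = ~np.eye(n, dtype=bool)
    if np.any(shared[off] == 0):
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValidationError(
            f"vectors {i} and {j} share no non-missing positions; "
            f"cannot compute a distance"
        )
    if metric == "correlation":
        r = pd.DataFrame(vecs.T).corr(method="pearson", min_periods=1).to_numpy()
        if np.isnan(r[off]).any():
            i, j = np.argwhere(np.isnan(r) & off)[0]
            raise ValidationError(
                f"vectors {i} and {j} have zero variance over shared positions; "
                f"correlation distance undefined"
            )
        d = 1.0 - r
    elif not mask.all():
        x0 = np.where(mask, vecs, 0.0)
        if metric == "euclidean":
            sq = x0**2
            s = sq @ mask.T + mask @ sq.T - 2.0 * (x0 @ x0.T)
            s = np.maximum(s, 0.0)
            d = np.sqrt(s * (t / shared))
        else:  # manhattan
            d = np.zeros((n, n))
            for i in range(n):
                diff = np.abs(vecs[i] - vecs[i + 1 :])
                both = mask[i] & mask[i + 1 :]
                sums = np.where(both, np.nan_to_num(diff), 0.0).sum(axis=1)
                row = sums * (t / shared[i, i + 1 :])
                d[i, i + 1 :] = row
                d[i + 1 :, i] = row
    else:
        scipy_name = {"euclidean": "euclidean", "manhattan": "cityblock"}[metric]
        d = squareform(pdist(vecs, metric=scipy_name))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0  # enforce exact symmetry


# ---------------------------------------------------------------------------
# agglomeration


def _linkage_to_merges(Z: np.ndarray, n: int) -> tuple[list[tuple[int, int]], list[float]]:
    """Convert a scipy linkage matrix to hclust-style merge pairs."""
    merges: list[tuple[int, int]] = []
    heights: list[float] = []
    for k in range(Z.shape[0]):
        refs = []
        for side in (0, 1):
            idx = int(Z[k, side])
            refs.append(-(idx + 1) if idx < n else idx - n + 1)
        refs.sort()  # leaves (negative) before merges, smaller first
        merges.append((refs[0], refs[1]))
        heights.append(float(Z[k, 2]))
    return merges, heights


def _leaf_order(merges: list[tuple[int, int]], n: int) -> list[int]:
    """Deterministic left-to-right order: the subtree containing the
    smallest original leaf index goes left at every merge."""
    if n == 1:
        return [0]
    min_leaf: dict[int, int] = {}
    leaves: dict[int, list[int]] = {}

    def resolve(ref: int) -> tuple[int, list[int]]:
        if ref < 0:
            leaf = -ref - 1
            return leaf, [leaf]
        return min_leaf[ref], leaves[ref]

    for k, (a, b) in enumerate(merges, start=1):
        ma, la = resolve(a)
        mb, lb = resolve(b)
        if ma <= mb:
            min_leaf[k], leaves[k] = ma, la + lb
        else:
            min_leaf[k], leaves[k] = mb, lb + la
    return leaves[len(merges)]


def cluster(m: LabeledMatrix, axis: str, spec: OrderSpec) -> Dendrogram:
    """Agglomeratively cluster one axis under ``spec``'s linkage/metric."""
    if spec.mode != "cluster":
        raise ValidationError("cluster() requires an OrderSpec with mode='cluster'")
    _check_axis(axis)
    n = len(m.labels(axis))
    if n < 2:
        return Dendrogram(merges=[], heights=[], leaf_order=list(range(n)) or [0][:n])
    d = distance_matrix(m, axis, spec.distance)
    condensed = squareform(d, checks=False)
    Z = _scipy_linkage(condensed, method=spec.linkage)
    merges, heights = _linkage_to_merges(Z, n)
    return Dendrogram(merges=merges, heights=heights, leaf_order=_leaf_order(merges, n))


def order_axis(
    m: LabeledMatrix, axis: str, spec: OrderSpec
) -> tuple[list[int], Dendrogram | None]:
    """Display permutation for one axis, plus the dendrogram when clustered."""
    _check_axis(axis)
    n = len(m.labels(axis))
    if spec.mode == "original":
        return list(range(n)), None
    if spec.mode == "random":
        rng = np.random.default_rng(spec.seed)
        return [int(i) for i in rng.permutation(n)], None
    dend = cluster(m, axis, spec)
    return list(dend.leaf_order), dend


def cut_top_branches(
    d: Dendrogram,
    k: int,
    labels: list[str] | None = None,
    axis: str = "col",
    name: str | None = None,
):
    """Discrete covariate from the top ``k`` branches of a dendrogram.

    Removing the k−1 highest merges leaves k subtrees; each leaf is
    assigned "Cluster 1".."Cluster k", numbered by first appearance in
    leaf order (left to right on the drawn map).
    """
    from chmforge.covariates import Covariate  # local import: avoid a cycle

    n = d.n_leaves
    if not (1 <= k <= n):
        raise ValidationError(f"k must be in 1..{n}, got {k}")
    if labels is None:
        labels = [str(i) for i in range(n)]
    # apply all merges except the k-1 highest (the last k-1 in merge order;
    # heights are non-decreasing for the supported linkages)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rep: dict[int, int] = {}  # merge id (1-based) -> representative leaf

    def leaf_of(ref: int) -> int:
        return -ref - 1 if ref < 0 else rep[ref]

    n_apply = len(d.merges) - (k - 1)
    for idx, (a, b) in enumerate(d.merges, start=1):
        la, lb = leaf_of(a), leaf_of(b)
        rep[idx] = la
        if idx <= n_apply:
            parent[find(lb)] = find(la)
    assign: dict[int, str] = {}
    next_id = 1
    values: dict[str, str] = {}
    for leaf in d.leaf_order:
        root = find(leaf)
        if root not in assign:
            assign[root] = f"Cluster {next_id}"
            next_id += 1
        values[labels[leaf]] = assign[root]
    return Covariate(name=name or f"Top {k} Branches", axis=axis, kind="discrete", values=values)
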