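"""Naive O(n^3) agglomerative clustering oracle.

A deliberately simple reference implementation used only in tests: at
every step it scans all active cluster pairs for the smallest distance,
merges, and recomputes inter-cluster distances from first principles —
single/complete/average directly from the original distance matrix,
Ward via the ward.D2 Lance-Williams recurrence on squared distances.
Entirely independent of scipy's nearest-neighbor-chain implementation.
"""

from __future__ import annotations

import numpy as np


def naive_pairwise_distance(vecs: np.ndarray, metric: str) -> np.ndarray:
    """Direct per-pair distance with pairwise-complete rescaling."""
    n, t = vecs.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = vecs[i], vecs[j]
            ok = ~(np.isnan(a) | np.isnan(b))
            s = ok.sum()
            if s == 0:
                raise ValueError(f"no shared positions for pair ({i}, {j})")
            if metric == "euclidean":
                val = np.sqrt(np.sum((a[ok] - b[ok]) ** 2) * t / s)
            elif metric == "manhattan":
                val = np.sum(np.abs(a[ok] - b[ok])) * t / s
            elif metric == "correlation":
                x, y = a[ok], b[ok]
                x = x - x.mean()
                y = y - y.mean()
                denom = np.sqrt((x**2).sum() * (y**2).sum())
                if denom == 0:
                    raise ValueError(f"zero variance for pair ({i}, {j})")
                val = 1.0 - float(np.dot(x, y) / denom)
            else:
                raise ValueError(metric)
            d[i, j] = d[j, i] = val
    return d


def naive_agglomerate(D: np.ndarray, method: str):
    """Agglomerate by exhaustive pair scan.

    Returns (heights, cophenetic) where ``heights`` is the sorted-by-
    merge-order list of merge distances and ``cophenetic`` the full
    matrix of heights at which each leaf pair is first joined.
    """
    n = D.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    coph = np.zeros((n, n))
    heights: list[float] = []
    next_id = n
    while len(members) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        for x in members[a]:
            for y in members[b]:
                coph[x, y] = coph[y, x] = h
        merged = members[a] + members[b]
        na, nb = len(members[a]), len(members[b])
        d_ab = dist.pop((a, b))
        del members[a], members[b]
        new_d: dict[int, float] = {}
        for c, mem_c in members.items():
            key_ac = (min(a, c), max(a, c))
            key_bc = (min(b, c), max(b, c))
            d_ac, d_bc = dist.pop(key_ac), dist.pop(key_bc)
            nc = len(mem_c)
            if method == "single":
                val = min(d_ac, d_bc)
            elif method == "complete":
                val = max(d_ac, d_bc)
            elif method == "average":
                val = (na * d_ac + nb * d_bc) / (na + nb)
            elif method == "ward":
                # ward.D2: Lance-Williams on squared distances
                val = np.sqrt(
                    ((na + nc) * d_ac**2 + (nb + nc) * d_bc**2 - nc * d_ab**2)
                    / (na + nb + nc)
                )
            else:
                raise ValueError(method)
            new_d[c] = float(val)
        members[next_id] = merged
        for c, val in new_d.items():
            dist[(min(c, next_id), max(c, next_id))] = val
        next_id += 1
    return heights, coph


def ward_centroid_height(members_a, members_b, X: np.ndarray) -> float:
    """Closed-form ward.D2 merge cost on Euclidean observations:
    sqrt(2 |A||B| / (|A|+|B|)) * ||mean_A - mean_B||."""
    a, b = X[list(members_a)], X[list(members_b)]
    na, nb = len(a), len(b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    return float(np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(diff))
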