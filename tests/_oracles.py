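"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain O(n²) loops over an explicit distance
matrix, deliberately sharing no code path with the package (which uses
kd-trees / ball trees / cumulative sums).
"""

from __future__ import annotations

import math

import numpy as np


def brute_dbscan(points: np.ndarray, radius: float, min_pts: int) -> np.ndarray:
    """Reference DBSCAN: core = >= min_pts within radius incl. self (d <= r);
    clusters = connected core points + border points; border joins the
    cluster of its lowest-index core neighbor; labels ordered by lowest core
    index; noise = -1."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    labels = [-1] * n
    if n == 0:
        return np.array(labels, dtype=np.int64)
    neighbors = []
    for i in range(n):
        nb = []
        for j in range(n):
            if math.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1]) <= radius:
                nb.append(j)
        neighbors.append(nb)
    core = [len(nb) >= min_pts for nb in neighbors]
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            j = queue.pop(0)
            for k in neighbors[j]:
                if core[k] and labels[k] == -1:
                    labels[k] = cluster
                    queue.append(k)
        cluster += 1
    for i in range(n):
        if core[i]:
            continue
        core_nb = [k for k in neighbors[i] if core[k]]
        if core_nb:
            labels[i] = labels[min(core_nb)]
    return np.array(labels, dtype=np.int64)


def brute_nearest_neighbor(points: np.ndarray) -> np.ndarray:
    """Reference nearest-neighbor distances by exhaustive search.

    Distances are sqrt(dx² + dy²) — the plain Euclidean formula, so values
    are bit-comparable with any exact index using the same arithmetic."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    out = np.empty(n)
    for i in range(n):
        best = math.inf
        for j in range(n):
            if i == j:
                continue
            dx = pts[i, 0] - pts[j, 0]
            dy = pts[i, 1] - pts[j, 1]
            best = min(best, math.sqrt(dx * dx + dy * dy))
        out[i] = best
    return out


def brute_ripley_k(points: np.ndarray, radii: np.ndarray,
                   roi: tuple[float, float, float, float],
                   edge_correction: str) -> np.ndarray:
    """Reference Ripley K by direct double-loop counting."""
    pts = np.asarray(points, dtype=float)
    xmin, ymin, xmax, ymax = roi
    w, h = xmax - xmin, ymax - ymin
    area = w * h
    keep = [(xmin <= x <= xmax) and (ymin <= y <= ymax) for x, y in pts]
    pts = pts[np.array(keep, dtype=bool)]
    n = len(pts)
    K = np.zeros(len(radii))
    for ri, r in enumerate(radii):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx = abs(pts[i, 0] - pts[j, 0])
                dy = abs(pts[i, 1] - pts[j, 1])
                if math.hypot(dx, dy) <= r:
                    if edge_correction == "translation":
                        total += area / ((w - dx) * (h - dy))
                    else:
                        total += 1.0
        K[ri] = area / (n * (n - 1)) * total
    return K


def brute_filter(rows: list[dict], efo_max: float, cfr_max: float, min_locs: int) -> list[dict]:
    """Reference row-by-row quality filter (strict >, then trace-length rule)."""
    survivors = [r for r in rows if not (r["efo_hz"] > efo_max or r["cfr"] > cfr_max)]
    counts: dict[int, int] = {}
    for r in survivors:
        counts[r["trace_id"]] = counts.get(r["trace_id"], 0) + 1
    return [r for r in survivors if counts[r["trace_id"]] >= min_locs]
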