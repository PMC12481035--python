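"""Point-pattern statistics on trace centers.

Everything downstream of trace-center estimation lives here: a deterministic
DBSCAN, exact nearest-neighbor distances, isolated-pair detection (the
operational signature of a receptor dimer: a DBSCAN cluster of exactly two
centers at a 40 nm search radius, which by chaining implies no third center
within the radius of either member), multi-center cluster characterization,
Ripley K/L/H with optional translation edge correction, and a Mann–Whitney
comparison for per-cell statistics across conditions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist
from scipy import stats
from sklearn.neighbors import BallTree

from .exceptions import ConfigurationError, DomainError, InsufficientDataError
from .io_formats import TraceCenterSet

logger = logging.getLogger(__name__)

NOISE = -1


def dbscan(points: np.ndarray, radius: float, min_pts: int) -> np.ndarray:
    """DBSCAN cluster labels; noise points get -1.

    Standard semantics with the conventions fixed as: a core point has
    >= ``min_pts`` points within ``radius`` *including itself*; the radius
    test is inclusive (d <= radius); clusters are connected core points plus
    border points; a border point reachable from several clusters joins the
    cluster of its lowest-index core neighbor. Labels are numbered by the
    lowest core-point index in each cluster, so the labeling is a pure
    function of the point set.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if radius <= 0:
        raise ConfigurationError("radius must be > 0")
    if min_pts < 1:
        raise ConfigurationError("min_pts must be >= 1")
    n = len(points)
    labels = np.full(n, NOISE, dtype=np.int64)
    if n == 0:
        return labels
    if not np.isfinite(points).all():
        raise DomainError("coordinates must be finite")
    # radius test is inclusive (d <= radius) on both paths
    if n <= 64:
        diff = points[:, None, :] - points[None, :, :]
        within = (diff**2).sum(axis=2) <= radius * radius
        neighborhoods = [np.flatnonzero(row) for row in within]
    else:
        tree = cKDTree(points)
        neighborhoods = tree.query_ball_point(points, r=radius)
    core = np.fromiter((len(nb) >= min_pts for nb in neighborhoods), dtype=bool, count=n)

    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        labels[i] = cluster
        stack = [i]
        while stack:
            j = stack.pop()
            for k in neighborhoods[j]:
                if core[k] and labels[k] == NOISE:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1

    for i in range(n):
        if core[i]:
            continue
        core_neighbors = [k for k in neighborhoods[i] if core[k]]
        if core_neighbors:
            labels[i] = labels[min(core_neighbors)]
    return labels


def nearest_neighbor_distances(centers: TraceCenterSet | np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each center to its closest other center.

    Backed by a ball tree; results are contractually identical to exhaustive
    search (the tree is an exact index, not an approximation).
    """
    pts = centers.coordinates if isinstance(centers, TraceCenterSet) else np.asarray(centers, dtype=float)
    if len(pts) < 2:
        raise InsufficientDataError("nearest-neighbor analysis needs at least 2 centers")
    tree = BallTree(pts)
    dist, _ = tree.query(pts, k=2)
    return dist[:, 1]


@dataclass
class PairSet:
    """Isolated pairs of trace centers and their geometry.

    ``pairs`` has one row per pair: member trace_ids, member coordinates,
    the exact member distance, the midpoint, and the distance from the pair
    to the nearest third center (always > search_radius, recorded as the
    verification of isolation).
    """

    pairs: pd.DataFrame
    search_radius: float

    @property
    def count(self) -> int:
        return len(self.pairs)

    @property
    def distances(self) -> np.ndarray:
        return self.pairs["distance_nm"].to_numpy(dtype=float)

    def summary(self) -> dict[str, Any]:
        d = self.distances
        return {
            "count": int(len(d)),
            "mean_distance_nm": float(d.mean()) if len(d) else None,
            "median_distance_nm": float(np.median(d)) if len(d) else None,
            "sd_distance_nm": float(d.std(ddof=1)) if len(d) > 1 else None,
            "distances_nm": [float(v) for v in d],
            "search_radius_nm": float(self.search_radius),
        }


_PAIR_COLUMNS = ["trace_id_a", "trace_id_b", "ax_nm", "ay_nm", "bx_nm", "by_nm",
                 "a_n_locs", "b_n_locs", "distance_nm", "mid_x_nm", "mid_y_nm", "third_nn_nm"]


def find_isolated_pairs(centers: TraceCenterSet, search_radius: float = 40.0) -> PairSet:
    """Detect isolated pairs: DBSCAN clusters of exactly 2 at ``search_radius``.

    With min_pts = 2 every member of a size-2 cluster is core, and chaining
    guarantees no third center lies within ``search_radius`` of either
    member — the two are mutual nearest neighbors. That guarantee is
    *verified* on every output (distance to the nearest third center is
    measured and asserted > search_radius), not re-filtered.
    """
    pts = centers.coordinates
    df = centers.df
    empty = pd.DataFrame(columns=_PAIR_COLUMNS)
    if len(pts) < 2:
        return PairSet(pairs=empty, search_radius=search_radius)
    labels = dbscan(pts, search_radius, min_pts=2)
    rows = []
    tree = cKDTree(pts) if len(pts) >= 3 else None
    for lbl, size in zip(*np.unique(labels[labels >= 0], return_counts=True)):
        if size != 2:
            continue
        i, j = np.flatnonzero(labels == lbl)
        dist = float(np.hypot(*(pts[i] - pts[j])))
        third = math.inf
        if tree is not None:
            for m, partner in ((i, j), (j, i)):
                dd, ii = tree.query(pts[m], k=3)
                for dv, iv in zip(dd, ii):
                    if iv != m and iv != partner:
                        third = min(third, float(dv))
                        break
        if not (dist <= search_radius and third > search_radius):
            raise AssertionError(
                "isolated-pair invariant violated: DBSCAN size-2 cluster with a "
                f"third center at {third:.3f} nm <= search radius"
            )
        rows.append((
            int(df["trace_id"].iloc[i]), int(df["trace_id"].iloc[j]),
            float(pts[i, 0]), float(pts[i, 1]), float(pts[j, 0]), float(pts[j, 1]),
            int(df["n_locs"].iloc[i]), int(df["n_locs"].iloc[j]),
            dist,
            float((pts[i, 0] + pts[j, 0]) / 2), float((pts[i, 1] + pts[j, 1]) / 2),
            third,
        ))
    pairs = pd.DataFrame(rows, columns=_PAIR_COLUMNS) if rows else empty
    logger.info("pairs: %d isolated pairs at %.1f nm search radius", len(pairs), search_radius)
    return PairSet(pairs=pairs, search_radius=search_radius)


@dataclass
class ClusterParams:
    """Cluster detection settings: DBSCAN radius (nm) and minimum composition."""

    search_radius: float = 40.0
    min_cluster_size: int = 4

    def __post_init__(self) -> None:
        if self.search_radius <= 0:
            raise ConfigurationError("search_radius must be > 0")
        if self.min_cluster_size < 2:
            raise ConfigurationError("min_cluster_size must be >= 2")


@dataclass
class ClusterSet:
    """Detected multi-center clusters with geometry summaries.

    Per cluster: composition (member count), size (maximum pairwise member
    distance, nm), convex-hull area (nm²; degenerate/collinear clusters fall
    back to a size × 1 nm ribbon and are flagged), density = composition/area.
    """

    clusters: pd.DataFrame
    members: dict[int, list[int]] = field(default_factory=dict)
    params: ClusterParams = field(default_factory=ClusterParams)

    @property
    def count(self) -> int:
        return len(self.clusters)

    def summary(self) -> dict[str, Any]:
        c = self.clusters
        return {
            "count": int(len(c)),
            "mean_composition": float(c["composition"].mean()) if len(c) else None,
            "mean_size_nm": float(c["size_nm"].mean()) if len(c) else None,
            "mean_density_per_nm2": float(c["density_per_nm2"].mean()) if len(c) else None,
            "search_radius_nm": float(self.params.search_radius),
            "min_cluster_size": int(self.params.min_cluster_size),
            "size_definition": "max pairwise member distance (diameter)",
            "density_definition": "composition / convex-hull area",
        }


_CLUSTER_COLUMNS = ["cluster_id", "composition", "size_nm", "area_nm2",
                    "density_per_nm2", "centroid_x_nm", "centroid_y_nm", "hull_degenerate"]


def _hull_area(points: np.ndarray, size_nm: float) -> tuple[float, bool]:
    """Convex-hull area; collinear/degenerate sets get a size × 1 nm ribbon."""
    unique = np.unique(points, axis=0)
    if len(unique) >= 3:
        try:
            hull = ConvexHull(unique)
            if hull.volume > 0:  # 2D: volume is the area
                return float(hull.volume), False
        except QhullError:
            pass
    return float(max(size_nm, 1.0) * 1.0), True


def cluster_analysis(centers: TraceCenterSet, params: ClusterParams | None = None) -> ClusterSet:
    """Characterize clusters of >= ``min_cluster_size`` centers.

    Clusters are DBSCAN components at ``search_radius`` with
    min_pts = ``min_cluster_size``; with that setting every component has at
    least min_cluster_size members, but composition is still checked.
    """
    if params is None:
        params = ClusterParams()
    pts = centers.coordinates
    ids = centers.df["trace_id"].to_numpy()
    empty = pd.DataFrame(columns=_CLUSTER_COLUMNS)
    if len(pts) == 0:
        return ClusterSet(clusters=empty, members={}, params=params)
    labels = dbscan(pts, params.search_radius, params.min_cluster_size)
    rows = []
    members: dict[int, list[int]] = {}
    out_id = 0
    for lbl in np.unique(labels[labels >= 0]):
        idx = np.flatnonzero(labels == lbl)
        if len(idx) < params.min_cluster_size:
            continue
        sub = pts[idx]
        size_nm = float(pdist(sub).max()) if len(idx) > 1 else 0.0
        area, degenerate = _hull_area(sub, size_nm)
        rows.append((
            out_id, int(len(idx)), size_nm, area, float(len(idx) / area),
            float(sub[:, 0].mean()), float(sub[:, 1].mean()), degenerate,
        ))
        members[out_id] = [int(t) for t in ids[idx]]
        out_id += 1
    clusters = pd.DataFrame(rows, columns=_CLUSTER_COLUMNS) if rows else empty
    logger.info("clusters: %d clusters (>=%d centers within %.1f nm)",
                len(clusters), params.min_cluster_size, params.search_radius)
    return ClusterSet(clusters=clusters, members=members, params=params)


@dataclass
class RipleyCurve:
    """Ripley K/L/H over a radius grid.

    H(r) = L(r) − r with L(r) = √(K(r)/π); H > 0 indicates clustering at
    scale r, H < 0 dispersion. ``edge_correction`` is ``none`` or
    ``translation`` (rectangular ROI).
    """

    radii: np.ndarray
    K: np.ndarray
    L: np.ndarray
    H: np.ndarray
    edge_correction: str
    n_points: int
    roi: tuple[float, float, float, float]

    def to_dict(self) -> dict[str, Any]:
        return {
            "radii_nm": [float(v) for v in self.radii],
            "K": [float(v) for v in self.K],
            "L": [float(v) for v in self.L],
            "H": [float(v) for v in self.H],
            "edge_correction": self.edge_correction,
            "n_points": int(self.n_points),
            "roi_nm": [float(v) for v in self.roi],
        }


def ripley_h(
    centers: TraceCenterSet | np.ndarray,
    radii: Sequence[float] | np.ndarray,
    roi: tuple[float, float, float, float],
    edge_correction: str = "translation",
) -> RipleyCurve:
    """Ripley K/L/H estimator on a rectangular ROI.

    K̂(r) = (A / (n(n−1))) Σ_{i≠j} e_ij · 1[d_ij ≤ r], with e_ij = 1 for no
    correction or the translation correction
    e_ij = A / ((w − |Δx_ij|)(h − |Δy_ij|)). Points outside the ROI are
    excluded. The largest radius must not exceed half the shorter ROI side.
    """
    pts = centers.coordinates if isinstance(centers, TraceCenterSet) else np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if edge_correction not in ("none", "translation"):
        raise ConfigurationError(f"unknown edge correction: {edge_correction!r}")
    if len(radii) == 0 or (radii <= 0).any() or (np.diff(radii) <= 0).any():
        raise DomainError("radii must be positive and strictly ascending")
    xmin, ymin, xmax, ymax = map(float, roi)
    w, h = xmax - xmin, ymax - ymin
    if w <= 0 or h <= 0:
        raise DomainError("ROI must have positive area")
    if radii.max() > min(w, h) / 2:
        raise DomainError(
            f"max radius {radii.max():.1f} nm exceeds half the shorter ROI side ({min(w, h) / 2:.1f} nm)"
        )
    inside = (pts[:, 0] >= xmin) & (pts[:, 0] <= xmax) & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax)
    pts = pts[inside]
    n = len(pts)
    if n < 2:
        raise InsufficientDataError("Ripley analysis needs at least 2 centers inside the ROI")
    area = w * h
    dx = np.abs(pts[:, 0, None] - pts[None, :, 0])
    dy = np.abs(pts[:, 1, None] - pts[None, :, 1])
    d = np.hypot(dx, dy)
    iu = ~np.eye(n, dtype=bool)
    # only pairs with d <= max radius can contribute; since max radius is at
    # most half the shorter ROI side, their translation weights are finite
    near = iu & (d <= radii.max())
    d_flat = d[near]
    if edge_correction == "translation":
        w_flat = area / ((w - dx[near]) * (h - dy[near]))
    else:
        w_flat = np.ones_like(d_flat)
    order = np.argsort(d_flat, kind="stable")
    d_sorted = d_flat[order]
    w_cum = np.concatenate([[0.0], np.cumsum(w_flat[order])])
    idx = np.searchsorted(d_sorted, radii, side="right")
    K = (area / (n * (n - 1))) * w_cum[idx]
    L = np.sqrt(K / math.pi)
    H = L - radii
    return RipleyCurve(radii=radii, K=K, L=L, H=H,
                       edge_correction=edge_correction, n_points=n,
                       roi=(xmin, ymin, xmax, ymax))


def csr_envelope(
    n_points: int,
    roi: tuple[float, float, float, float],
    radii: Sequence[float] | np.ndarray,
    n_sims: int = 100,
    level: float = 0.95,
    edge_correction: str = "translation",
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Pointwise Monte-Carlo envelope of H(r) under complete spatial randomness.

    Simulates ``n_sims`` binomial (fixed-n uniform) patterns in the ROI and
    returns the pointwise lower/upper quantiles and mean of H(r) — the null
    band against which observed clustering is judged.
    """
    if rng is None:
        rng = np.random.default_rng()
    xmin, ymin, xmax, ymax = map(float, roi)
    radii = np.asarray(radii, dtype=float)
    curves = np.empty((n_sims, len(radii)))
    for s in range(n_sims):
        pts = np.column_stack([
            rng.uniform(xmin, xmax, n_points),
            rng.uniform(ymin, ymax, n_points),
        ])
        curves[s] = ripley_h(pts, radii, roi, edge_correction).H
    alpha = (1.0 - level) / 2.0
    return {
        "radii": radii,
        "lower": np.quantile(curves, alpha, axis=0),
        "upper": np.quantile(curves, 1.0 - alpha, axis=0),
        "mean": curves.mean(axis=0),
        "curves": curves,
    }


def _mannwhitney_u(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def compare_conditions(sample_a: Sequence[float], sample_b: Sequence[float]) -> dict[str, Any]:
    """Two-sided Mann–Whitney U test between two sets of per-cell statistics.

    For small samples (both n <= 8) the p-value is exact, by enumeration of
    all C(n_a + n_b, n_a) group assignments of the midranks (ties handled
    naturally); otherwise the normal approximation with tie correction is
    used (scipy). Returns U (for sample_a), the p-value, and the method.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u_obs = _mannwhitney_u(ranks[:n_a], n_a)
    if n_a <= 8 and n_b <= 8:
        mu = n_a * n_b / 2.0
        dev = abs(u_obs - mu)
        total = 0
        extreme = 0
        for subset in itertools.combinations(range(n_a + n_b), n_a):
            u = _mannwhitney_u(ranks[list(subset)], n_a)
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                extreme += 1
        p = extreme / total
        method = "exact-enumeration"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal-approximation"
    return {"U": u_obs, "p_value": float(min(p, 1.0)), "method": method,
            "n_a": n_a, "n_b": n_b}
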