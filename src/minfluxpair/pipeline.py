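"""End-to-end orchestration: (simulate | read) → filter → trace centers →
pairs → clusters → nearest neighbors → Ripley H, plus recovery scoring of
detections against simulated ground truth.

One localization table is one cell/ROI; condition-level comparisons consume
per-cell summaries (see :func:`minfluxpair.spatial.compare_conditions`).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .exceptions import ConfigurationError, ConsistencyError, StageError
from .io_formats import (
    LocalizationTable,
    TraceCenterSet,
    read_localizations,
    write_ground_truth,
    write_localizations,
    write_report,
    write_trace_centers,
)
from .preprocess import FilterParams, TraceCenterParams, compute_trace_centers, filter_localizations
from .spatial import (
    ClusterParams,
    RipleyCurve,
    cluster_analysis,
    find_isolated_pairs,
    nearest_neighbor_distances,
    ripley_h,
)
from .synthetic import GroundTruth, SimulationConfig, simulate_ground_truth, simulate_localizations

logger = logging.getLogger(__name__)


@dataclass
class RipleySettings:
    """Radius grid and edge handling for the Ripley stage."""

    r_max: float = 200.0
    r_step: float = 5.0
    edge_correction: str = "translation"
    roi: tuple[float, float, float, float] | None = None  # default: centers' bounding box

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.r_step <= 0 or self.r_step > self.r_max:
            raise ConfigurationError("require 0 < r_step <= r_max")
        if self.edge_correction not in ("none", "translation"):
            raise ConfigurationError(f"unknown edge correction: {self.edge_correction!r}")

    def radii(self, r_max: float | None = None) -> np.ndarray:
        top = self.r_max if r_max is None else min(self.r_max, r_max)
        return np.arange(self.r_step, top + self.r_step / 2, self.r_step)


@dataclass
class PipelineConfig:
    """Full configuration for one pipeline run (one cell/ROI).

    Exactly one of ``input_path`` (a localization CSV) or ``simulation``
    (generator parameters) provides the input. All analysis defaults are the
    standard acquisition-analysis values: efo 50,000 Hz / cfr 0.95 / 3 locs,
    trace DBSCAN 4 nm / 3, pair and cluster search radius 40 nm, minimum
    cluster composition 4.
    """

    filter: FilterParams = field(default_factory=FilterParams)
    trace_center: TraceCenterParams = field(default_factory=TraceCenterParams)
    clusters: ClusterParams = field(default_factory=ClusterParams)
    pair_search_radius: float = 40.0
    ripley: RipleySettings = field(default_factory=RipleySettings)
    input_path: str | None = None
    simulation: SimulationConfig | None = None
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair_search_radius <= 0:
            raise ConfigurationError("pair_search_radius must be > 0")
        if (self.input_path is None) == (self.simulation is None):
            raise ConfigurationError("exactly one of input_path or simulation must be set")

    def to_dict(self) -> dict[str, Any]:
        return {
            "filter": asdict(self.filter),
            "trace_center": asdict(self.trace_center),
            "clusters": asdict(self.clusters),
            "pair_search_radius": self.pair_search_radius,
            "ripley": {
                "r_max": self.ripley.r_max,
                "r_step": self.ripley.r_step,
                "edge_correction": self.ripley.edge_correction,
                "roi": list(self.ripley.roi) if self.ripley.roi else None,
            },
            "input_path": self.input_path,
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        if data.get("filter"):
            kwargs["filter"] = FilterParams(**data["filter"])
        if data.get("trace_center"):
            kwargs["trace_center"] = TraceCenterParams(**data["trace_center"])
        if data.get("clusters"):
            kwargs["clusters"] = ClusterParams(**data["clusters"])
        if "pair_search_radius" in data:
            kwargs["pair_search_radius"] = data["pair_search_radius"]
        if data.get("ripley"):
            rip = dict(data["ripley"])
            if rip.get("roi"):
                rip["roi"] = tuple(rip["roi"])
            kwargs["ripley"] = RipleySettings(**rip)
        if data.get("simulation"):
            sim = dict(data["simulation"])
            sim.setdefault("seed", data.get("seed", 0))
            kwargs["simulation"] = SimulationConfig.from_dict(sim)
        for key in ("input_path", "output_dir", "seed"):
            if data.get(key) is not None:
                kwargs[key] = data[key]
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SummaryReport:
    """Everything one pipeline run measures, plus provenance.

    ``pairs`` keeps the full per-pair geometry (member coordinates and
    distances) so recovery scoring and condition-level pooling need no
    re-analysis; both the pooled-pair and per-cell views of the distance
    summary can be built from it.
    """

    stage_counts: dict[str, int]
    pair_summary: dict[str, Any]
    pairs: list[dict[str, Any]]
    cluster_summary: dict[str, Any]
    clusters: list[dict[str, Any]]
    mean_nn_distance_nm: float | None
    median_nn_distance_nm: float | None
    ripley: RipleyCurve | None
    provenance: dict[str, Any]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "stage_counts": self.stage_counts,
            "pair_summary": self.pair_summary,
            "pairs": self.pairs,
            "cluster_summary": self.cluster_summary,
            "clusters": self.clusters,
            "mean_nn_distance_nm": self.mean_nn_distance_nm,
            "median_nn_distance_nm": self.median_nn_distance_nm,
            "ripley": self.ripley.to_dict() if self.ripley is not None else None,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _empty_summary(kind: str) -> dict[str, Any]:
    if kind == "pairs":
        return {"count": 0, "mean_distance_nm": None, "median_distance_nm": None,
                "sd_distance_nm": None, "distances_nm": [], "search_radius_nm": None}
    return {"count": 0, "mean_composition": None, "mean_size_nm": None,
            "mean_density_per_nm2": None}


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Run the full analysis chain for one cell/ROI; deterministic given config.

    An empty or fully-filtered input produces a zeroed report with a warning
    rather than an error. Every stage logs its counts; any stage failure is
    re-raised as :class:`StageError` naming the stage.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report_warnings: list[str] = []

    truth: GroundTruth | None = None
    try:
        if config.simulation is not None:
            truth = simulate_ground_truth(config.simulation)
            table = simulate_localizations(truth, config.simulation)
            if out_dir:
                write_ground_truth(truth, out_dir / "truth.csv")
                meta = {k: v for k, v in table.metadata.items() if k != "trace_source_mol_ids"}
                write_localizations(LocalizationTable(df=table.df, metadata=meta), out_dir / "locs.csv")
        else:
            table = read_localizations(config.input_path)  # type: ignore[arg-type]
    except Exception as exc:  # noqa: BLE001
        raise StageError("input", exc) from exc

    try:
        filtered = filter_localizations(table, config.filter)
        if out_dir:
            write_localizations(
                LocalizationTable(
                    df=filtered.df,
                    metadata={k: v for k, v in filtered.metadata.items()
                              if np.isscalar(v) or isinstance(v, str)},
                ),
                out_dir / "filtered.csv",
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter", exc) from exc

    try:
        centers = compute_trace_centers(filtered, config.trace_center)
        if out_dir:
            write_trace_centers(centers, out_dir / "centers.csv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("trace_centers", exc) from exc

    stage_counts = {
        "localizations_in": int(filtered.metadata.get("localizations_in", len(table.df))),
        "localizations_after_filter": len(filtered.df),
        "traces_in": int(filtered.metadata.get("traces_in", table.n_traces)),
        "traces_after_filter": int(filtered.metadata.get("traces_out", filtered.n_traces)),
        "centers": len(centers),
    }

    if len(centers) == 0:
        msg = "no trace centers survive filtering; report contains zeroed statistics"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
        report_warnings.append(msg)

    try:
        pair_set = find_isolated_pairs(centers, config.pair_search_radius)
        pair_summary = pair_set.summary() if len(centers) else _empty_summary("pairs")
        pair_rows = pair_set.pairs.to_dict(orient="records")
    except Exception as exc:  # noqa: BLE001
        raise StageError("pairs", exc) from exc

    try:
        cluster_set = cluster_analysis(centers, config.clusters)
        cluster_summary = cluster_set.summary() if len(centers) else _empty_summary("clusters")
        cluster_rows = cluster_set.clusters.to_dict(orient="records")
    except Exception as exc:  # noqa: BLE001
        raise StageError("clusters", exc) from exc

    try:
        if len(centers) >= 2:
            nn = nearest_neighbor_distances(centers)
            mean_nn, median_nn = float(nn.mean()), float(np.median(nn))
        else:
            mean_nn = median_nn = None
            if len(centers) > 0:
                report_warnings.append("fewer than 2 centers; nearest-neighbor analysis skipped")
    except Exception as exc:  # noqa: BLE001
        raise StageError("nearest_neighbors", exc) from exc

    try:
        curve = _ripley_stage(centers, config, report_warnings)
    except Exception as exc:  # noqa: BLE001
        raise StageError("ripley", exc) from exc

    provenance: dict[str, Any] = {
        "config": config.to_dict(),
        "seed": config.seed if config.simulation is None else config.simulation.seed,
        "version": __version__,
    }
    if config.simulation is not None:
        provenance["field_bounds_nm"] = list(config.simulation.field_bounds)
        provenance["true_pair_separation_nm"] = config.simulation.pair_separation_d

    report = SummaryReport(
        stage_counts=stage_counts,
        pair_summary=pair_summary,
        pairs=pair_rows,
        cluster_summary=cluster_summary,
        clusters=cluster_rows,
        mean_nn_distance_nm=mean_nn,
        median_nn_distance_nm=median_nn,
        ripley=curve,
        provenance=provenance,
        warnings=report_warnings,
    )
    if out_dir:
        write_report(report, out_dir / "report.json")
    logger.info("pipeline: %d centers, %d pairs, %d clusters",
                len(centers), pair_summary["count"], cluster_summary["count"])
    return report


def _ripley_stage(centers: TraceCenterSet, config: PipelineConfig,
                  report_warnings: list[str]) -> RipleyCurve | None:
    if len(centers) < 2:
        report_warnings.append("fewer than 2 centers; Ripley analysis skipped")
        return None
    settings = config.ripley
    if settings.roi is not None:
        roi = settings.roi
    else:
        pts = centers.coordinates
        roi = (float(pts[:, 0].min()), float(pts[:, 1].min()),
               float(pts[:, 0].max()), float(pts[:, 1].max()))
    short_side = min(roi[2] - roi[0], roi[3] - roi[1])
    if short_side <= 2 * settings.r_step:
        report_warnings.append("ROI too small for the Ripley radius grid; Ripley analysis skipped")
        return None
    radii = settings.radii(r_max=short_side / 2)
    if len(radii) < len(settings.radii()):
        report_warnings.append(
            f"Ripley radius grid clipped to {radii.max():.1f} nm (half the shorter ROI side)"
        )
    return ripley_h(centers, radii, roi, settings.edge_correction)


@dataclass
class RecoveryMetrics:
    """How well detections recovered the simulated truth.

    A detected pair matches a true dimer when each detected center lies
    within ``match_tolerance`` of a distinct member (greedy closest-first
    matching). With zero detections, precision is reported as 1.0 with
    ``precision_undefined`` flagged — no false positives among zero
    detections; recall is over *all* true dimers, so sub-100% labeling caps
    it near p_label².
    """

    pair_precision: float
    pair_recall: float
    precision_undefined: bool
    pair_distance_bias_nm: float | None
    cluster_count_recall: float
    n_detected_pairs: int
    n_true_dimers: int
    n_matched_pairs: int
    match_tolerance_nm: float

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _pair_match_cost(pair: dict[str, Any], members: np.ndarray) -> float:
    """Best assignment cost (max center-to-member distance) over the two bijections."""
    a = np.array([pair["ax_nm"], pair["ay_nm"]])
    b = np.array([pair["bx_nm"], pair["by_nm"]])
    d = lambda p, q: float(np.hypot(*(p - q)))
    return min(
        max(d(a, members[0]), d(b, members[1])),
        max(d(a, members[1]), d(b, members[0])),
    )


def evaluate_recovery(truth: GroundTruth, report: SummaryReport,
                      match_tolerance: float = 10.0,
                      cluster_match_tolerance: float = 30.0) -> RecoveryMetrics:
    """Score detected pairs and clusters against the generating ground truth."""
    bounds = report.provenance.get("field_bounds_nm")
    if bounds is not None and tuple(bounds) != tuple(truth.field_bounds):
        raise ConsistencyError(
            f"report field bounds {bounds} do not match ground truth {truth.field_bounds}"
        )

    dimer_groups: dict[int, np.ndarray] = {
        int(gid): g[["x_nm", "y_nm"]].to_numpy(dtype=float)
        for gid, g in truth.groups("dimer")
    }
    n_true = len(dimer_groups)

    candidates = []
    for p_idx, pair in enumerate(report.pairs):
        for gid, members in dimer_groups.items():
            cost = _pair_match_cost(pair, members)
            if cost <= match_tolerance:
                candidates.append((cost, p_idx, gid))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    matched_pairs: set[int] = set()
    matched_groups: set[int] = set()
    matched_distances: list[float] = []
    for cost, p_idx, gid in candidates:
        if p_idx in matched_pairs or gid in matched_groups:
            continue
        matched_pairs.add(p_idx)
        matched_groups.add(gid)
        matched_distances.append(float(report.pairs[p_idx]["distance_nm"]))

    n_detected = len(report.pairs)
    n_matched = len(matched_pairs)
    precision_undefined = n_detected == 0
    precision = 1.0 if precision_undefined else n_matched / n_detected
    recall = 1.0 if n_true == 0 else n_matched / n_true

    true_d = report.provenance.get("true_pair_separation_nm")
    if true_d is None and dimer_groups:
        members = next(iter(dimer_groups.values()))
        true_d = float(np.hypot(*(members[0] - members[1])))
    bias = float(np.mean(matched_distances) - true_d) if matched_distances and true_d is not None else None

    cluster_centroids = np.array([
        g[["x_nm", "y_nm"]].to_numpy(dtype=float).mean(axis=0)
        for _, g in truth.groups("cluster")
    ])
    n_true_clusters = len(cluster_centroids)
    if n_true_clusters == 0:
        cluster_recall = 1.0
    else:
        detected = np.array([[c["centroid_x_nm"], c["centroid_y_nm"]] for c in report.clusters])
        c_candidates = []
        for i, det in enumerate(detected):
            dists = np.hypot(*(cluster_centroids - det).T)
            for j in np.flatnonzero(dists <= cluster_match_tolerance):
                c_candidates.append((float(dists[j]), i, int(j)))
        c_candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        used_d: set[int] = set()
        used_t: set[int] = set()
        for _, i, j in c_candidates:
            if i in used_d or j in used_t:
                continue
            used_d.add(i)
            used_t.add(j)
        cluster_recall = len(used_t) / n_true_clusters

    return RecoveryMetrics(
        pair_precision=float(precision),
        pair_recall=float(recall),
        precision_undefined=precision_undefined,
        pair_distance_bias_nm=bias,
        cluster_count_recall=float(cluster_recall),
        n_detected_pairs=n_detected,
        n_true_dimers=n_true,
        n_matched_pairs=n_matched,
        match_tolerance_nm=float(match_tolerance),
    )


def pooled_pair_distances(reports: list[SummaryReport]) -> dict[str, Any]:
    """Pool pair distances across cells; report both pooling conventions.

    ``pooled_*`` treats every pair as one observation regardless of cell;
    ``per_cell_mean_of_means`` averages each cell's mean first. Both are
    exposed because pooling weights change the condition-level number when
    cells contribute unequal pair counts.
    """
    all_d = np.concatenate([
        np.asarray(r.pair_summary["distances_nm"], dtype=float) for r in reports
    ]) if reports else np.array([])
    cell_means = [r.pair_summary["mean_distance_nm"] for r in reports
                  if r.pair_summary["mean_distance_nm"] is not None]
    return {
        "n_cells": len(reports),
        "n_pairs": int(len(all_d)),
        "pooled_mean_nm": float(all_d.mean()) if len(all_d) else None,
        "pooled_median_nm": float(np.median(all_d)) if len(all_d) else None,
        "pooled_sd_nm": float(all_d.std(ddof=1)) if len(all_d) > 1 else None,
        "per_cell_mean_of_means_nm": float(np.mean(cell_means)) if cell_means else None,
    }
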