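"""Localization quality filtering and trace-center estimation.

A raw MINFLUX table is reduced in two stages. First, per-localization
quality cuts: localizations with background-corrected emission rate (efo)
strictly above ``efo_max`` or center-frequency ratio (cfr) strictly above
``cfr_max`` are removed, then whole traces that retain fewer than
``min_locs_per_trace`` localizations are dropped. Second, each surviving
trace is collapsed to a single 2D trace center by running DBSCAN on its own
localizations and averaging the largest cluster — one fluorophore has one
true position, so satellite localizations and noise never contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io_formats import LocalizationTable, TraceCenterSet
from .spatial import dbscan

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Quality thresholds; values exactly at a threshold are kept (cuts are strict >)."""

    efo_max: float = 50_000.0
    cfr_max: float = 0.95
    min_locs_per_trace: int = 3

    def __post_init__(self) -> None:
        if self.efo_max <= 0 or self.cfr_max <= 0:
            raise ConfigurationError("efo_max and cfr_max must be > 0")
        if self.min_locs_per_trace < 1:
            raise ConfigurationError("min_locs_per_trace must be >= 1")


@dataclass
class TraceCenterParams:
    """Per-trace DBSCAN settings (radius in nm; min_pts counts the point itself)."""

    dbscan_radius: float = 4.0
    dbscan_min_pts: int = 3

    def __post_init__(self) -> None:
        if self.dbscan_radius <= 0:
            raise ConfigurationError("dbscan_radius must be > 0")
        if self.dbscan_min_pts < 1:
            raise ConfigurationError("dbscan_min_pts must be >= 1")


def filter_localizations(table: LocalizationTable, params: FilterParams | None = None) -> LocalizationTable:
    """Apply the quality filters; returns a new table, original untouched.

    Order matters and is fixed: the per-localization efo/cfr cuts run first,
    then traces whose *surviving* localization count falls below
    ``min_locs_per_trace`` are removed entirely. Row order is preserved and
    removal counts are recorded in the output metadata. Idempotent.
    """
    if params is None:
        params = FilterParams()
    df = table.df
    keep = (df["efo_hz"].to_numpy() <= params.efo_max) & (df["cfr"].to_numpy() <= params.cfr_max)
    n_loc_removed = int((~keep).sum())
    surviving = df[keep]
    counts = surviving.groupby("trace_id", sort=False)["trace_id"].transform("size")
    good_trace = counts >= params.min_locs_per_trace
    n_traces_removed = int(surviving.loc[~good_trace, "trace_id"].nunique())
    out = surviving[good_trace].reset_index(drop=True)
    metadata = dict(table.metadata)
    metadata.update({
        "filter_params": asdict(params),
        "localizations_in": len(df),
        "localizations_removed_quality": n_loc_removed,
        "localizations_removed_short_trace": int(len(surviving) - len(out)),
        "traces_in": int(df["trace_id"].nunique()),
        "traces_removed_short": n_traces_removed,
        "localizations_out": len(out),
        "traces_out": int(out["trace_id"].nunique()),
    })
    logger.info(
        "filter: %d -> %d localizations (%d quality cut, %d in short traces); %d -> %d traces",
        len(df), len(out), n_loc_removed, len(surviving) - len(out),
        metadata["traces_in"], metadata["traces_out"],
    )
    return LocalizationTable(df=out, metadata=metadata)


def _trace_center(sub: pd.DataFrame, params: TraceCenterParams) -> tuple[float, float, int] | None:
    """Center of one trace: mean of the largest DBSCAN cluster, or None.

    Ties between equal-size largest clusters are broken toward the cluster
    containing the earliest-time localization. Rows are put in canonical
    (time, x, y) order first so the result is invariant to input row order.
    """
    sub = sub.sort_values(["time", "x_nm", "y_nm"], kind="mergesort")
    pts = sub[["x_nm", "y_nm"]].to_numpy(dtype=float)
    labels = dbscan(pts, params.dbscan_radius, params.dbscan_min_pts)
    if (labels < 0).all():
        return None
    valid = labels >= 0
    sizes = np.bincount(labels[valid])
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size)
    if len(candidates) == 1:
        best = candidates[0]
    else:
        # earliest-time member wins (rows are time-sorted)
        first_member = [np.flatnonzero(labels == c)[0] for c in candidates]
        best = candidates[int(np.argmin(first_member))]
    members = pts[labels == best]
    # mean about the first member: exact when all points coincide (noiseless
    # data) and better conditioned for large absolute coordinates
    ref = members[0]
    cx, cy = ref + (members - ref).mean(axis=0)
    return float(cx), float(cy), int(best_size)


def compute_trace_centers(table: LocalizationTable, params: TraceCenterParams | None = None) -> TraceCenterSet:
    """Collapse each trace to a single center via per-trace DBSCAN.

    Traces whose localizations form no DBSCAN cluster (no core point) yield
    no center and are dropped. Deterministic; DBSCAN runs per trace, never
    across traces, so nearby distinct emitters are not conflated.
    """
    if params is None:
        params = TraceCenterParams()
    rows = []
    n_dropped = 0
    for trace_id, sub in table.df.groupby("trace_id", sort=False):
        result = _trace_center(sub, params)
        if result is None:
            n_dropped += 1
            continue
        cx, cy, n_locs = result
        rows.append((int(trace_id), n_locs, cx, cy))
    df = pd.DataFrame(rows, columns=["trace_id", "n_locs", "x_nm", "y_nm"])
    if not rows:
        df = df.astype({"trace_id": np.int64, "n_locs": np.int64, "x_nm": float, "y_nm": float})
    provenance = dict(table.metadata)
    provenance.update({
        "trace_center_params": asdict(params),
        "traces_without_center": n_dropped,
        "n_centers": len(df),
    })
    logger.info("centers: %d traces -> %d centers (%d traces had no cluster)",
                table.df["trace_id"].nunique() if len(table.df) else 0, len(df), n_dropped)
    return TraceCenterSet(df=df, provenance=provenance)
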