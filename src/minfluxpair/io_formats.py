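"""Plain-text readers and writers for localization tables, trace centers,
ground-truth sidecars, Ripley curves, and analysis reports.

The canonical interchange format is CSV with an explicit header. Metadata
travels in ``#``-prefixed ``key = value`` comment lines above the header.
Coordinates are always nanometers in the 2D imaging plane; a ``z_nm``
column, if present, is ignored with a warning (synapses are flat and the
acquisition is 2D).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError

logger = logging.getLogger(__name__)

LOCALIZATION_COLUMNS = ["trace_id", "time", "x_nm", "y_nm", "efo_hz", "cfr"]
CENTER_COLUMNS = ["trace_id", "n_locs", "x_nm", "y_nm"]
TRUTH_COLUMNS = ["mol_id", "x_nm", "y_nm", "class", "group_id", "labeled"]
RIPLEY_COLUMNS = ["r_nm", "K", "L", "H"]

_INT_COLUMNS = {"trace_id", "n_locs", "mol_id", "group_id", "labeled"}


@dataclass
class LocalizationTable:
    """Per-emission-event localizations with quality metrics.

    ``df`` has columns ``trace_id, time, x_nm, y_nm, efo_hz, cfr``; all
    localizations sharing a ``trace_id`` form one trace (one emission event
    of one fluorophore). ``metadata`` is free-form provenance (field-of-view
    bounds in nm, condition label, generator seed, ...).
    """

    df: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in LOCALIZATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"localization table missing column(s): {', '.join(missing)}")
        self.df = self.df[LOCALIZATION_COLUMNS].reset_index(drop=True)

    def validate(self) -> None:
        df = self.df
        for col in ("x_nm", "y_nm"):
            if not np.isfinite(df[col].to_numpy(dtype=float)).all():
                raise FormatError(f"non-finite values in column {col}")
        if (df["efo_hz"].to_numpy(dtype=float) < 0).any():
            raise FormatError("efo_hz must be >= 0")
        if (df["cfr"].to_numpy(dtype=float) < 0).any():
            raise FormatError("cfr must be >= 0")
        bounds = self.fov_bounds()
        if bounds is not None and len(df):
            xmin, ymin, xmax, ymax = bounds
            x, y = df["x_nm"].to_numpy(), df["y_nm"].to_numpy()
            if x.min() < xmin or x.max() > xmax or y.min() < ymin or y.max() > ymax:
                raise FormatError("coordinates fall outside declared field-of-view bounds")

    def fov_bounds(self) -> tuple[float, float, float, float] | None:
        keys = ("fov_xmin_nm", "fov_ymin_nm", "fov_xmax_nm", "fov_ymax_nm")
        if all(k in self.metadata for k in keys):
            return tuple(float(self.metadata[k]) for k in keys)  # type: ignore[return-value]
        return None

    @property
    def n_localizations(self) -> int:
        return len(self.df)

    @property
    def n_traces(self) -> int:
        return self.df["trace_id"].nunique()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocalizationTable):
            return NotImplemented
        return self.df.equals(other.df)


def _write_metadata(handle, metadata: dict[str, Any]) -> None:
    for key, value in metadata.items():
        handle.write(f"# {key} = {value!r}\n")


def _read_metadata(path: Path) -> dict[str, Any]:
    meta: dict[str, Any] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    meta[key.strip()] = eval(value.strip(), {"__builtins__": {}})  # literals only
                except Exception:
                    meta[key.strip()] = value.strip()
    return meta


def _read_csv(path: str | Path, required: list[str], what: str) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} file {path} is missing required column '{col}'")
    extra = [c for c in df.columns if c not in required]
    if "z_nm" in extra:
        logger.warning("ignoring z_nm column in %s (2D analysis)", path)
        warnings.warn(f"ignoring z_nm column in {path} (2D analysis)", stacklevel=3)
    out = {}
    for col in required:
        if col == "class":
            out[col] = df[col].astype(str)
            continue
        # parse with Python's float(): correctly rounded, so written values
        # round-trip bit-identically (pandas' fast parser is off by 1 ulp)
        values = np.empty(len(df))
        for row, cell in enumerate(df[col]):
            if pd.isna(cell):
                raise ParseError(f"missing value in column '{col}' at data row {row + 1} of {path}")
            try:
                values[row] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} in column '{col}' at data row {row + 1} of {path}"
                ) from None
        out[col] = values.astype(np.int64) if col in _INT_COLUMNS else values
    return pd.DataFrame(out, index=range(len(df))), meta


def read_localizations(path: str | Path, dialect: str = "generic-csv") -> LocalizationTable:
    """Read a localization table. Row order and trace grouping are preserved.

    The only supported dialect is ``generic-csv`` (header
    ``trace_id,time,x_nm,y_nm,efo_hz,cfr``); vendor exports should be
    converted to it upstream.
    """
    if dialect != "generic-csv":
        raise FormatError(f"unknown localization dialect: {dialect!r}")
    df, meta = _read_csv(path, LOCALIZATION_COLUMNS, "localization")
    return LocalizationTable(df=df, metadata=meta)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a localization table as CSV (full float precision; round-trip exact)."""
    path = Path(path)
    with open(path, "w") as fh:
        _write_metadata(fh, table.metadata)
        table.df.to_csv(fh, index=False)


@dataclass
class TraceCenterSet:
    """One 2D point per accepted fluorophore trace.

    ``df`` has columns ``trace_id, n_locs, x_nm, y_nm``; ``provenance``
    records the filter/center parameters and per-stage removal counts.
    """

    df: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CENTER_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"trace-center set missing column(s): {', '.join(missing)}")
        self.df = self.df[CENTER_COLUMNS].reset_index(drop=True)
        if self.df["trace_id"].duplicated().any():
            raise FormatError("trace-center set has duplicate trace_ids")

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 2) array of center coordinates in nm."""
        return self.df[["x_nm", "y_nm"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)


def read_trace_centers(path: str | Path) -> TraceCenterSet:
    df, meta = _read_csv(path, CENTER_COLUMNS, "trace-center")
    return TraceCenterSet(df=df, provenance=meta)


def write_trace_centers(centers: TraceCenterSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_metadata(fh, {k: v for k, v in centers.provenance.items() if np.isscalar(v)})
        centers.df.to_csv(fh, index=False)


def read_ground_truth(path: str | Path):
    from .synthetic import GroundTruth

    df, meta = _read_csv(path, TRUTH_COLUMNS, "ground-truth")
    bounds = tuple(meta.get(k, np.nan) for k in ("field_xmin_nm", "field_ymin_nm", "field_xmax_nm", "field_ymax_nm"))
    df["labeled"] = df["labeled"].astype(bool)
    return GroundTruth(molecules=df, field_bounds=bounds)  # type: ignore[arg-type]


def write_ground_truth(truth, path: str | Path) -> None:
    path = Path(path)
    xmin, ymin, xmax, ymax = truth.field_bounds
    meta = {"field_xmin_nm": xmin, "field_ymin_nm": ymin, "field_xmax_nm": xmax, "field_ymax_nm": ymax}
    df = truth.molecules.copy()
    df["labeled"] = df["labeled"].astype(int)
    with open(path, "w") as fh:
        _write_metadata(fh, meta)
        df.to_csv(fh, index=False)


def write_ripley_csv(curve, path: str | Path) -> None:
    """Write a Ripley curve as CSV with header ``r_nm,K,L,H``."""
    df = pd.DataFrame(
        {"r_nm": curve.radii, "K": curve.K, "L": curve.L, "H": curve.H}
    )
    df.to_csv(path, index=False)


def read_ripley_csv(path: str | Path) -> pd.DataFrame:
    df, _ = _read_csv(path, RIPLEY_COLUMNS, "Ripley curve")
    return df


def write_report(report, path: str | Path) -> None:
    """Write a SummaryReport as JSON; the Ripley curve is additionally
    emitted next to it as ``<stem>_ripley.csv``."""
    path = Path(path)
    payload = report.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if report.ripley is not None:
        write_ripley_csv(report.ripley, path.with_name(path.stem + "_ripley.csv"))


def read_report(path: str | Path) -> dict[str, Any]:
    """Read a report JSON back as a plain dict (round-trips write_report)."""
    with open(path) as fh:
        return json.load(fh)
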