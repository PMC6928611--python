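"""Sensor-log readers, stream alignment, and the deployment container.

All three inputs are plain CSV with ISO-8601 timestamps:

* GPS log — ``timestamp, lat, lon, animal_id`` (one fix per row);
* accelerometer log — ``timestamp, location, ax, ay, az`` (one row per
  logger per tick; location is neck, leg or tail);
* behavior labels — ``timestamp, behavior`` (grazing or nongrazing).

Readers validate the schema, parse timestamps as timezone-aware UTC,
reject malformed rows (counting and logging them) and sort by time.
``align_streams`` puts everything on the GPS grid: each accelerometer
channel and label is matched to its nearest fix within a tolerance
(strictly less than ``tolerance_s``); unmatched slots are missing, and
recording gaps longer than cadence + tolerance split the trajectory
into segments so that no movement metric ever spans a gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accel import AXES, LOCATIONS, AccelSeries
from .geo import Trajectory

logger = logging.getLogger("grazetrack")

VALID_BEHAVIORS = ("grazing", "nongrazing")


class SchemaError(ValueError):
    """Input file is missing a required column."""


@dataclass
class Deployment:
    """One animal's aligned streams on a common strictly-increasing grid."""

    trajectory: Trajectory
    accel: AccelSeries
    labels: np.ndarray  # object array: "grazing" / "nongrazing" / None

    def __post_init__(self) -> None:
        n = len(self.trajectory)
        if len(self.accel) != n or len(self.labels) != n:
            raise ValueError("trajectory, accel and labels must share one grid")
        if not self.trajectory.timestamps.equals(self.accel.timestamps):
            raise ValueError("trajectory and accel timestamp grids differ")

    def __len__(self) -> int:
        return len(self.trajectory)

    def label_mask(self) -> np.ndarray:
        return np.array([l in VALID_BEHAVIORS for l in self.labels])


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _parse_timestamps(df: pd.DataFrame, path) -> tuple[pd.DataFrame, int]:
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = ts.isna()
    for line in df.index[bad]:
        logger.warning("%s: unparseable timestamp at data row %d", path, line + 2)
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    return df, int(bad.sum())


def read_gps(path) -> pd.DataFrame:
    """Read and validate a GPS log; returns a sorted frame.

    The number of rejected rows is recorded in ``df.attrs["n_rejected"]``.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["timestamp", "lat", "lon", "animal_id"], path)
    if len(df) == 0:
        logger.warning("%s: zero data rows", path)
    df, n_bad = _parse_timestamps(df, path)
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    ok = (
        df["lat"].between(-90, 90)
        & df["lon"].between(-180, 180)
        & df["lat"].notna()
        & df["lon"].notna()
    )
    for line in df.index[~ok]:
        logger.warning("%s: coordinate out of range at data row %d", path, line + 2)
    n_bad += int((~ok).sum())
    df = df.loc[ok].sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)
    df.attrs["n_rejected"] = n_bad
    return df


def read_accel(path) -> pd.DataFrame:
    """Read and validate an accelerometer log (long form, one row per logger)."""
    df = pd.read_csv(path)
    _require_columns(df, ["timestamp", "location", "ax", "ay", "az"], path)
    if len(df) == 0:
        logger.warning("%s: zero data rows", path)
    df, n_bad = _parse_timestamps(df, path)
    for c in ("ax", "ay", "az"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = (
        df["location"].isin(LOCATIONS)
        & np.isfinite(df[["ax", "ay", "az"]]).all(axis=1)
    )
    for line in df.index[~ok]:
        logger.warning("%s: invalid accelerometer row at data row %d", path, line + 2)
    n_bad += int((~ok).sum())
    df = df.loc[ok].sort_values(["location", "timestamp"], kind="stable").reset_index(drop=True)
    df.attrs["n_rejected"] = n_bad
    return df


def read_labels(path) -> pd.DataFrame:
    """Read and validate a behavior-label log."""
    df = pd.read_csv(path)
    _require_columns(df, ["timestamp", "behavior"], path)
    if len(df) == 0:
        logger.warning("%s: zero data rows", path)
    df, n_bad = _parse_timestamps(df, path)
    ok = df["behavior"].isin(VALID_BEHAVIORS)
    for line in df.index[~ok]:
        logger.warning("%s: unknown behavior at data row %d", path, line + 2)
    n_bad += int((~ok).sum())
    df = df.loc[ok].sort_values("timestamp", kind="stable").reset_index(drop=True)
    df.attrs["n_rejected"] = n_bad
    return df


def _nearest_match(grid: pd.DatetimeIndex, other: pd.DataFrame, value_cols, tolerance_s: float):
    """Nearest-timestamp join of ``other`` onto ``grid``, strict tolerance."""
    left = pd.DataFrame({"timestamp": grid})
    right = other.sort_values("timestamp")
    tol = pd.Timedelta(seconds=tolerance_s) - pd.Timedelta(1, "ns")
    merged = pd.merge_asof(
        left, right, on="timestamp", direction="nearest", tolerance=tol
    )
    return merged[value_cols]


def segment_ids_from_gaps(
    timestamps: pd.DatetimeIndex, cadence_s: float = 50.0, tolerance_s: float = 5.0
) -> np.ndarray:
    """Split a fix sequence at gaps longer than cadence + tolerance."""
    if len(timestamps) == 0:
        return np.empty(0, dtype=int)
    dt = np.diff(timestamps.asi8) / 1e9
    breaks = dt > (cadence_s + tolerance_s)
    return np.r_[0, np.cumsum(breaks)].astype(int)


def align_streams(
    gps: pd.DataFrame,
    accel: pd.DataFrame,
    labels: pd.DataFrame,
    cadence_s: float = 50.0,
    tolerance_s: float = 5.0,
    forced_zone: int | None = None,
) -> Deployment:
    """Align all streams onto the GPS fix grid of one animal.

    The GPS timestamps define the grid.  Accelerometer channels and
    labels are matched by nearest timestamp within ``tolerance_s``
    (half-open: an offset equal to the tolerance does not match);
    unmatched slots are missing.  Gaps longer than cadence + tolerance
    split the trajectory into segments.
    """
    if len(gps) == 0:
        raise ValueError("at least one GPS fix is required")
    animals = gps["animal_id"].unique()
    if len(animals) > 1:
        raise ValueError(f"align_streams handles one animal at a time, got {list(animals)}")

    gps = gps.sort_values("timestamp", kind="stable").reset_index(drop=True)
    grid = pd.DatetimeIndex(gps["timestamp"])
    seg = segment_ids_from_gaps(grid, cadence_s, tolerance_s)
    traj = Trajectory.from_latlon(
        animal_id=str(animals[0]),
        timestamps=grid,
        lat=gps["lat"].to_numpy(),
        lon=gps["lon"].to_numpy(),
        segment_ids=seg,
        forced_zone=forced_zone,
        cadence_s=cadence_s,
    )

    channels = {}
    for loc in LOCATIONS:
        sub = accel.loc[accel["location"] == loc, ["timestamp", "ax", "ay", "az"]]
        matched = _nearest_match(grid, sub, ["ax", "ay", "az"], tolerance_s)
        for axis, col in zip(AXES, ("ax", "ay", "az")):
            channels[f"{loc}_{axis}"] = matched[col].to_numpy(dtype=float)
    accel_series = AccelSeries(timestamps=grid, channels=pd.DataFrame(channels))

    lab = _nearest_match(grid, labels[["timestamp", "behavior"]], ["behavior"], tolerance_s)
    label_arr = lab["behavior"].where(lab["behavior"].notna(), None).to_numpy(dtype=object)

    n_missing_accel = int(np.isnan(accel_series.channels.to_numpy()).any(axis=1).sum())
    n_missing_label = int(sum(l is None for l in label_arr))
    logger.info(
        "aligned %d fixes (%d segments, %d fixes with missing accel, %d without label)",
        len(grid), seg.max() + 1 if len(seg) else 0, n_missing_accel, n_missing_label,
    )
    return Deployment(trajectory=traj, accel=accel_series, labels=label_arr)
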