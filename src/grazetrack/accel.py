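"""Tri-axial accelerometer posture features.

Each animal carries three loggers (neck, leg, tail) recording
acceleration along the superior–inferior (x), anteroposterior (y) and
transverse (z) body axes at the same 50-s cadence as the GPS.  For each
timestamp the feature table holds 24 model columns:

* the 9 raw channels ``raw_<loc>_<axis>`` (m/s²),
* 3 vector magnitudes ``M_<loc>`` = sqrt(ax² + ay² + az²),
* 9 windowed standard deviations ``SD_<loc>_<axis>`` (population
  divisor, 7-sample centered window),
* 3 overall dynamic body accelerations ``ODBA_<loc>``.

The raw signal at 50-s resolution is split into a *static* component —
the running mean over a centered 7-sample window (3 fixes ≈ 2.5 min on
each side plus the focal fix), attributed to posture/gravity — and a
*dynamic* residual attributed to movement.  ODBA is the sum of the
absolute dynamic components over the three axes of one logger.  Near
the ends of a series the window shrinks to the available samples and
the row is flagged (``edge_flag``); static/dynamic components are kept
in the output for audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

LOCATIONS = ("neck", "leg", "tail")
AXES = ("x", "y", "z")

#: half-width of the centered running window: 3 samples (2.5 min) each side
WINDOW_HALF = 3
WINDOW = 2 * WINDOW_HALF + 1

FEATURE_COLUMNS: list[str] = (
    [f"raw_{l}_{a}" for l in LOCATIONS for a in AXES]
    + [f"M_{l}" for l in LOCATIONS]
    + [f"SD_{l}_{a}" for l in LOCATIONS for a in AXES]
    + [f"ODBA_{l}" for l in LOCATIONS]
)


@dataclass
class AccelSeries:
    """Nine acceleration channels on a shared 50-s timestamp grid."""

    timestamps: pd.DatetimeIndex
    channels: pd.DataFrame  # columns "<loc>_<axis>", m/s^2

    def __post_init__(self) -> None:
        expected = [f"{l}_{a}" for l in LOCATIONS for a in AXES]
        missing = [c for c in expected for _ in [0] if c not in self.channels.columns]
        if missing:
            raise ValueError(f"missing accelerometer channels: {missing}")
        if len(self.channels) != len(self.timestamps):
            raise ValueError("channel length must match timestamp grid")
        self.channels = self.channels[expected]

    def __len__(self) -> int:
        return len(self.timestamps)

    def channel(self, location: str, axis: str) -> np.ndarray:
        return self.channels[f"{location}_{axis}"].to_numpy(dtype=float)


def magnitude(ax: float, ay: float, az: float) -> float:
    """Euclidean norm of one logger's axis triple; NaN if any axis missing."""
    if any(map(math.isnan, (ax, ay, az))):
        return math.nan
    return math.sqrt(ax * ax + ay * ay + az * az)


def _window_slice(n: int, focal: int) -> slice:
    if not (0 <= focal < n):
        raise IndexError(f"focal index {focal} outside series of length {n}")
    return slice(max(0, focal - WINDOW_HALF), min(n, focal + WINDOW_HALF + 1))


def static_acceleration(series: np.ndarray, focal: int) -> float:
    """Running-mean static component at ``focal`` (shrunken window at edges)."""
    x = np.asarray(series, dtype=float)
    w = x[_window_slice(len(x), focal)]
    w = w[~np.isnan(w)]
    if w.size == 0:
        return math.nan
    return float(w.mean())


def dynamic_acceleration(series: np.ndarray, focal: int) -> float:
    """Raw minus static at ``focal``; NaN propagates."""
    x = np.asarray(series, dtype=float)
    raw = float(x[focal])
    if math.isnan(raw):
        return math.nan
    return raw - static_acceleration(x, focal)


def windowed_sd(series: np.ndarray, focal: int) -> float:
    """Population standard deviation over the 7-sample centered window."""
    x = np.asarray(series, dtype=float)
    w = x[_window_slice(len(x), focal)]
    w = w[~np.isnan(w)]
    if w.size == 0:
        return math.nan
    return float(w.std(ddof=0))


def odba(ax_series, ay_series, az_series, focal: int) -> float:
    """Overall dynamic body acceleration for one logger at ``focal``.

    Sum of absolute dynamic (raw − running-mean static) components over
    the three axes; NaN if any axis is missing at the focal timestamp.
    """
    parts = [
        dynamic_acceleration(np.asarray(s, dtype=float), focal)
        for s in (ax_series, ay_series, az_series)
    ]
    if any(math.isnan(p) for p in parts):
        return math.nan
    return float(sum(abs(p) for p in parts))


def _rolling_static_sd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized centered running mean and population SD with shrunken edges."""
    s = pd.Series(x)
    r = s.rolling(WINDOW, center=True, min_periods=1)
    mean = r.mean().to_numpy()
    # population variance from the raw second moment
    m2 = (s * s).rolling(WINDOW, center=True, min_periods=1).mean().to_numpy()
    var = np.maximum(m2 - mean * mean, 0.0)
    return mean, np.sqrt(var)


def build_accel_features(accel: AccelSeries) -> pd.DataFrame:
    """Full posture feature table: 24 model columns plus audit columns.

    Model columns are listed in :data:`FEATURE_COLUMNS`; the frame also
    carries ``static_<loc>_<axis>`` and ``dyn_<loc>_<axis>`` for audit
    and an ``edge_flag`` marking rows whose running window was shrunk.
    """
    n = len(accel)
    out: dict[str, np.ndarray] = {}
    for loc in LOCATIONS:
        tri = {a: accel.channel(loc, a) for a in AXES}
        for a in AXES:
            out[f"raw_{loc}_{a}"] = tri[a]
        out[f"M_{loc}"] = np.sqrt(tri["x"] ** 2 + tri["y"] ** 2 + tri["z"] ** 2)
        dyn_abs_sum = np.zeros(n)
        odba_ok = np.ones(n, dtype=bool)
        for a in AXES:
            static, sd = _rolling_static_sd(tri[a])
            dyn = tri[a] - static
            out[f"SD_{loc}_{a}"] = sd
            out[f"static_{loc}_{a}"] = static
            out[f"dyn_{loc}_{a}"] = dyn
            dyn_abs_sum = dyn_abs_sum + np.abs(dyn)
            odba_ok &= ~np.isnan(tri[a])
        out[f"ODBA_{loc}"] = np.where(odba_ok, dyn_abs_sum, np.nan)

    edge = np.zeros(n, dtype=bool)
    edge[: min(WINDOW_HALF, n)] = True
    edge[max(0, n - WINDOW_HALF):] = True

    df = pd.DataFrame(out, index=np.arange(n))
    audit = [c for c in df.columns if c.startswith(("static_", "dyn_"))]
    df = df[FEATURE_COLUMNS + audit]
    df.insert(0, "timestamp", accel.timestamps)
    df["edge_flag"] = edge
    return df
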