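"""Synthetic labeled deployments: behavior states, movement, accelerations.

No field data accompany the analysis this package reproduces, so every
downstream stage is exercised on simulated deployments with the same
statistical structure the method assumes:

* a two-state behavior process (grazing ≈ 80% of fixes, nongrazing the
  rest) with geometric dwell times on the 50-s logging grid;
* a state-dependent correlated random walk in projected meters —
  grazing animals drift slowly but steadily while foraging; nongrazing
  fixes are mostly stationary (small isotropic apparent movement) with
  occasional fast, directed walking bouts;
* nine Gaussian accelerometer channels whose means depend on state,
  with the neck anteroposterior (y) channel configured as the main
  posture discriminant (well below −3 m/s² while the head is lowered to
  graze, near zero otherwise).

The generator is the ground truth for parameter-recovery tests: class
mix, displacement separation between states, and the posture
discriminant are all recoverable quantities with known values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .accel import AXES, LOCATIONS, AccelSeries
from .geo import Trajectory, from_utm, to_utm
from .io import Deployment

GRAZING = "grazing"
NONGRAZING = "nongrazing"
STATES = (GRAZING, NONGRAZING)


class InvalidConfigError(ValueError):
    """Simulation configuration violates an invariant."""


def _default_accel_mean() -> dict:
    """State-dependent emission means (m/s²) per (location, axis).

    The x (superior–inferior) axis carries gravity on every logger; the
    neck y (anteroposterior) axis is the posture discriminant: a lowered
    grazing head tips the logger so the channel reads strongly negative.
    All other channels are state-independent.
    """
    mean = {
        loc: {ax: {GRAZING: 0.0, NONGRAZING: 0.0} for ax in AXES} for loc in LOCATIONS
    }
    for loc in LOCATIONS:
        mean[loc]["x"] = {GRAZING: -9.8, NONGRAZING: -9.8}
    mean["neck"]["y"] = {GRAZING: -5.0, NONGRAZING: -0.3}
    return mean


def _default_accel_sd() -> dict:
    return {loc: {ax: {s: 1.0 for s in STATES} for ax in AXES} for loc in LOCATIONS}


@dataclass
class SimConfig:
    """Full generative specification of one synthetic deployment.

    Dwell means are in seconds on the ``cadence_s`` grid; the implied
    stationary grazing fraction ``dwell_g / (dwell_g + dwell_ng)`` must
    match ``grazing_target_fraction`` (enforced at construction).  Step
    parameters are meters per 50-s step; turning concentrations are the
    inverse-variance of the wrapped-normal heading increment (infinite
    concentration walks a straight line).
    """

    seed: int = 0
    n_fixes: int = 10_000
    cadence_s: float = 50.0
    grazing_target_fraction: float = 0.8
    dwell_mean_grazing_s: float = 1200.0
    dwell_mean_nongrazing_s: float = 300.0
    step_mean_grazing_m: float = 2.75
    step_sd_grazing_m: float = 1.5
    rest_prob_nongrazing: float = 0.8
    step_mean_rest_m: float = 4.0
    step_sd_rest_m: float = 1.2
    step_mean_walk_m: float = 25.0
    step_sd_walk_m: float = 8.0
    turn_concentration_grazing: float = 4.0
    turn_concentration_walk: float = 50.0
    jitter_mean_m: float = 4.0
    jitter_sd_m: float = 1.2
    accel_mean: Mapping = field(default_factory=_default_accel_mean)
    accel_sd: Mapping = field(default_factory=_default_accel_sd)
    origin_lat: float = 42.9167   # 42°55' N
    origin_lon: float = 120.7     # 120°42' E

    def __post_init__(self) -> None:
        if self.n_fixes < 2:
            raise InvalidConfigError("n_fixes must be >= 2")
        if self.cadence_s <= 0:
            raise InvalidConfigError("cadence_s must be positive")
        for name in ("grazing_target_fraction", "rest_prob_nongrazing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "step_sd_grazing_m",
            "step_sd_rest_m",
            "step_sd_walk_m",
            "step_mean_grazing_m",
            "step_mean_rest_m",
            "step_mean_walk_m",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        for dwell in (self.dwell_mean_grazing_s, self.dwell_mean_nongrazing_s):
            if not math.isinf(dwell) and dwell < self.cadence_s:
                raise InvalidConfigError("dwell means must be >= cadence_s")
        implied = self._implied_grazing_fraction()
        if abs(implied - self.grazing_target_fraction) > 1e-9:
            raise InvalidConfigError(
                "dwell means imply a stationary grazing fraction of "
                f"{implied:.6f}, which disagrees with grazing_target_fraction="
                f"{self.grazing_target_fraction}"
            )
        for loc in LOCATIONS:
            for ax in AXES:
                for s in STATES:
                    try:
                        mu = self.accel_mean[loc][ax][s]
                        sd = self.accel_sd[loc][ax][s]
                    except (KeyError, TypeError) as exc:
                        raise InvalidConfigError(
                            f"missing accelerometer emission for ({loc}, {ax}, {s})"
                        ) from exc
                    if sd < 0:
                        raise InvalidConfigError("accel_sd entries must be >= 0")
                    if not np.isfinite(mu):
                        raise InvalidConfigError("accel_mean entries must be finite")

    def _implied_grazing_fraction(self) -> float:
        g, ng = self.dwell_mean_grazing_s, self.dwell_mean_nongrazing_s
        if math.isinf(g) and math.isinf(ng):
            raise InvalidConfigError("at most one dwell mean may be infinite")
        if math.isinf(g):
            return 1.0
        if math.isinf(ng):
            return 0.0
        return g / (g + ng)

    @classmethod
    def balanced(cls, grazing_target_fraction: float, dwell_mean_nongrazing_s: float, **kw) -> "SimConfig":
        """Config with the grazing dwell mean derived from the target mix."""
        f = grazing_target_fraction
        if not (0.0 < f < 1.0):
            raise InvalidConfigError("target fraction must be in (0, 1) here")
        dwell_g = dwell_mean_nongrazing_s * f / (1.0 - f)
        return cls(
            grazing_target_fraction=f,
            dwell_mean_grazing_s=dwell_g,
            dwell_mean_nongrazing_s=dwell_mean_nongrazing_s,
            **kw,
        )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % 2**31, stream])


def simulate_states(config: SimConfig) -> np.ndarray:
    """Alternating-renewal behavior sequence with geometric dwells.

    Dwell lengths in ticks are geometric with mean ``dwell_mean / cadence``;
    the initial state is drawn from the stationary distribution.
    """
    rng = _rng(config, 0)
    n = config.n_fixes
    mean_ticks = {
        GRAZING: config.dwell_mean_grazing_s / config.cadence_s,
        NONGRAZING: config.dwell_mean_nongrazing_s / config.cadence_s,
    }
    frac = config._implied_grazing_fraction()
    state = GRAZING if rng.random() < frac else NONGRAZING
    out = np.empty(n, dtype=object)
    pos = 0
    while pos < n:
        m = mean_ticks[state]
        dwell = n - pos if math.isinf(m) else int(rng.geometric(1.0 / m))
        end = min(pos + dwell, n)
        out[pos:end] = state
        pos = end
        state = NONGRAZING if state == GRAZING else GRAZING
    return out


def _lognormal_steps(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Moment-matched lognormal step lengths; degenerate when sd == 0."""
    if size == 0:
        return np.empty(0)
    if mean == 0.0:
        return np.zeros(size)
    if sd == 0.0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _heading_sigma(concentration: float) -> float:
    if concentration <= 0:
        raise InvalidConfigError("turn concentrations must be positive")
    return 0.0 if math.isinf(concentration) else 1.0 / math.sqrt(concentration)


def nongrazing_modes(states: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-tick movement mode: grazing, rest, or walk.

    The rest/walk choice is made once per nongrazing *bout* so that
    walking bouts inherit the configured dwell scale — the time scale
    the interval-sweep recovery rests on.
    """
    n = len(states)
    modes = np.array(["graze"] * n, dtype=object)
    is_ng = states == NONGRAZING
    # bout boundaries
    starts = np.flatnonzero(is_ng & ~np.r_[False, is_ng[:-1]])
    for s in starts:
        e = s
        while e < n and is_ng[e]:
            e += 1
        mode = "rest" if rng.random() < config.rest_prob_nongrazing else "walk"
        modes[s:e] = mode
    return modes


def simulate_movement(states: np.ndarray, config: SimConfig) -> Trajectory:
    """State-dependent correlated random walk anchored at the site origin.

    Grazing: small lognormal steps with tortuous heading; nongrazing
    bouts either rest (tiny isotropic apparent movement) or walk (large
    steps, nearly straight).  Positions are produced in UTM meters and
    inverse-projected to latitude/longitude.
    """
    rng = _rng(config, 1)
    n = len(states)
    modes = nongrazing_modes(states, config, rng)

    # Anchor-plus-scatter kinematics.  Each state moves an *anchor* (the
    # animal's true position): grazing advances it by small lognormal
    # steps along a persistent heading (a slowly drifting foraging-patch
    # center), walking by large near-straight steps, resting freezes it.
    # Observed fixes scatter isotropically around the anchor — the
    # apparent movement of an animal observed at 50-s fix spacing
    # (``jitter_*`` for moving states, the rest-step kernel while
    # stationary).  Consequently short-window displacements of grazing
    # and resting fixes are nearly indistinguishable (both dominated by
    # scatter) while long-window displacements diverge linearly with the
    # grazing drift — the time-interval structure the downstream model
    # has to discover.
    graze_steps = _lognormal_steps(rng, config.step_mean_grazing_m, config.step_sd_grazing_m, n)
    rest_radii = _lognormal_steps(rng, config.step_mean_rest_m, config.step_sd_rest_m, n)
    walk_steps = _lognormal_steps(rng, config.step_mean_walk_m, config.step_sd_walk_m, n)
    jitter_radii = _lognormal_steps(rng, config.jitter_mean_m, config.jitter_sd_m, n)
    sigma_g = _heading_sigma(config.turn_concentration_grazing)
    sigma_w = _heading_sigma(config.turn_concentration_walk)
    incr = rng.normal(0.0, 1.0, n)
    uni = rng.uniform(-math.pi, math.pi, n)

    origin = to_utm(config.origin_lat, config.origin_lon)
    easting = np.empty(n)
    northing = np.empty(n)
    h = rng.uniform(0.0, 2.0 * math.pi)
    anchor_e, anchor_n = origin.easting, origin.northing
    for k in range(n):
        mode = modes[k]
        if mode == "rest":
            radius = rest_radii[k]
        else:
            if k > 0:
                if mode == "walk":
                    h = h + sigma_w * incr[k]
                    step = walk_steps[k]
                else:
                    h = h + sigma_g * incr[k]
                    step = graze_steps[k]
                anchor_e += step * math.cos(h)
                anchor_n += step * math.sin(h)
            radius = jitter_radii[k]
        easting[k] = anchor_e + radius * math.cos(uni[k])
        northing[k] = anchor_n + radius * math.sin(uni[k])
    lat, lon = from_utm(easting, northing, origin.zone, origin.hemisphere)

    t0 = pd.Timestamp("2018-09-23 09:00:00", tz="UTC")
    timestamps = t0 + pd.to_timedelta(np.arange(n) * config.cadence_s, unit="s")
    return Trajectory(
        animal_id="sim",
        timestamps=pd.DatetimeIndex(timestamps),
        easting=easting,
        northing=northing,
        zone=origin.zone,
        hemisphere=origin.hemisphere,
        segment_ids=np.zeros(n, dtype=int),
        lat=np.asarray(lat),
        lon=np.asarray(lon),
        cadence_s=config.cadence_s,
    )


def simulate_accel(states: np.ndarray, config: SimConfig) -> AccelSeries:
    """Nine independent Gaussian channels with state-dependent moments."""
    rng = _rng(config, 2)
    n = len(states)
    is_g = states == GRAZING
    cols = {}
    for loc in LOCATIONS:
        for ax in AXES:
            mu = np.where(
                is_g, config.accel_mean[loc][ax][GRAZING], config.accel_mean[loc][ax][NONGRAZING]
            )
            sd = np.where(
                is_g, config.accel_sd[loc][ax][GRAZING], config.accel_sd[loc][ax][NONGRAZING]
            )
            cols[f"{loc}_{ax}"] = mu + sd * rng.normal(0.0, 1.0, n)
    t0 = pd.Timestamp("2018-09-23 09:00:00", tz="UTC")
    timestamps = pd.DatetimeIndex(t0 + pd.to_timedelta(np.arange(n) * config.cadence_s, unit="s"))
    return AccelSeries(timestamps=timestamps, channels=pd.DataFrame(cols))


def simulate_deployment(config: SimConfig) -> Deployment:
    """Compose states, movement and accelerations into one deployment."""
    states = simulate_states(config)
    traj = simulate_movement(states, config)
    accel = simulate_accel(states, config)
    return Deployment(trajectory=traj, accel=accel, labels=states)


# --------------------------------------------------------------------------
# CSV writers (the dialects the readers in grazetrack.io expect)
# --------------------------------------------------------------------------


def write_deployment_csvs(dep: Deployment, out_dir) -> dict:
    """Write gps.csv, accel.csv (long form) and labels.csv into ``out_dir``."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts = dep.trajectory.timestamps

    gps = pd.DataFrame(
        {
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "lat": dep.trajectory.lat,
            "lon": dep.trajectory.lon,
            "animal_id": dep.trajectory.animal_id,
        }
    )
    gps.to_csv(out / "gps.csv", index=False)

    frames = []
    for loc in LOCATIONS:
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S%z"),
                    "location": loc,
                    "ax": dep.accel.channel(loc, "x"),
                    "ay": dep.accel.channel(loc, "y"),
                    "az": dep.accel.channel(loc, "z"),
                }
            )
        )
    pd.concat(frames).to_csv(out / "accel.csv", index=False)

    labels = pd.DataFrame(
        {"timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S%z"), "behavior": dep.labels}
    )
    labels.to_csv(out / "labels.csv", index=False)
    return {"gps": out / "gps.csv", "accel": out / "accel.csv", "labels": out / "labels.csv"}


# --------------------------------------------------------------------------
# Generative ground truth for recovery tests
# --------------------------------------------------------------------------


def displacement_by_state(config: SimConfig, interval_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Backward linear displacements at one interval, split by state.

    Simulates a fresh deployment from ``config`` and returns the lag-
    ``interval_s/cadence`` straight-line displacement for fixes whose
    backward window is entirely in one state (grazing vs nongrazing).
    """
    lag = int(interval_s // config.cadence_s)
    states = simulate_states(config)
    traj = simulate_movement(states, config)
    e, n = traj.easting, traj.northing
    disp = np.hypot(e[lag:] - e[:-lag], n[lag:] - n[:-lag])
    is_g = (states == GRAZING).astype(int)
    win_all_g = np.ones(len(disp), dtype=bool)
    win_all_ng = np.ones(len(disp), dtype=bool)
    for k in range(lag + 1):
        s = is_g[k : k + len(disp)]
        win_all_g &= s == 1
        win_all_ng &= s == 0
    return disp[win_all_g], disp[win_all_ng]


def generative_posterior_curve(
    config: SimConfig,
    interval_s: float,
    grid_size: int = 50,
    grid_percentiles=(5.0, 95.0),
    exclude_walk: bool = True,
):
    """Monte-Carlo posterior P(nongrazing | backward displacement).

    The generative analogue of a fitted model's partial-dependence
    curve: displacements from a fresh simulation are binned onto the
    same percentile grid convention, and the empirical nongrazing
    fraction per bin is returned as a curve.  Applying the same plateau
    rule to this curve gives the generative displacement threshold a
    recovered model threshold is compared against.

    By default windows touching a walking bout are excluded: the
    threshold of interest is the "distance beyond which nongrazing
    becomes unlikely", i.e. the rest-vs-graze transition, and walking
    displacements sit far beyond it, where a partial-dependence curve
    no longer tracks the 1-D posterior.
    """
    from .forest import PartialDependenceCurve

    lag = int(interval_s // config.cadence_s)
    states = simulate_states(config)
    traj = simulate_movement(states, config)
    e, n = traj.easting, traj.northing
    disp = np.hypot(e[lag:] - e[:-lag], n[lag:] - n[:-lag])
    lab = states[lag:]  # state at the focal fix
    if exclude_walk:
        modes = nongrazing_modes(states, config, _rng(config, 1))
        is_walk = (modes == "walk").astype(int)
        touches_walk = np.zeros(len(disp), dtype=bool)
        for k in range(lag + 1):
            touches_walk |= is_walk[k : k + len(disp)] == 1
        disp, lab = disp[~touches_walk], lab[~touches_walk]
    lo, hi = np.percentile(disp, grid_percentiles)
    grid = np.linspace(lo, hi, grid_size)
    # assign each displacement to its nearest grid point
    idx = np.clip(np.searchsorted(grid, disp), 0, grid_size - 1)
    left = np.maximum(idx - 1, 0)
    idx = np.where(np.abs(grid[left] - disp) < np.abs(grid[idx] - disp), left, idx)
    probs = np.full(grid_size, np.nan)
    ng = (lab == NONGRAZING).astype(float)
    for g in range(grid_size):
        m = idx == g
        if m.sum() > 0:
            probs[g] = ng[m].mean()
    probs = pd.Series(probs).interpolate(limit_direction="both").to_numpy()
    return PartialDependenceCurve(feature="blin_%d" % lag, grid=grid, prob_nongrazing=probs)
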