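"""The mechanistic dispersal core: d = v * p realized on GPS trajectories.

For each simulated seed, a deposition endpoint is drawn uniformly from the
individual's GPS fixes, a passage time p is drawn from the pooled retention
distribution, the ingestion start point is reconstructed on the trajectory
at (endpoint time - p), and the dispersal distance is the straight-line
displacement between start and end: horizontal in the plane, vertical in
elevation. Long-distance dispersal (LDD) is the fraction of simulated seeds
beyond an absolute threshold (1000 m horizontal; +/-50 m vertical), tallied
per (individual, month) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import Trajectory

EVENT_COLUMNS = ["animal_id", "month", "passage_h", "start_e", "start_n",
                 "start_z", "end_e", "end_n", "end_z", "d_horiz_m", "d_vert_m"]

ORIENTATIONS = ("horizontal", "upward", "downward")


@dataclass
class SimulationInfo:
    """Bookkeeping for one individual's event simulation."""

    animal_id: str
    n_requested: int
    n_events: int
    n_dropped: int

    @property
    def dropped_fraction(self) -> float:
        return self.n_dropped / self.n_requested if self.n_requested else 0.0


def sample_endpoints(traj: Trajectory, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` endpoint fixes uniformly with replacement from a trajectory.

    Endpoints are actual GPS fixes (with their timestamps), i.e. a random
    selection of possible seed deposition sites, not interpolated positions.
    """
    if len(traj) < 2:
        raise ValueError(f"{traj.animal_id}: trajectory needs >= 2 fixes")
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = rng.integers(0, len(traj), n)
    return pd.DataFrame({
        "timestamp": traj.times[idx],
        "easting": traj.easting[idx],
        "northing": traj.northing[idx],
        "elevation": traj.elevation[idx],
    })


def locate_start(traj: Trajectory, t_start) -> tuple[float, float, float] | None:
    """Locate a single start time on the trajectory; None if unresolved.

    Times within the tracking window are linearly interpolated in easting,
    northing and elevation between the bracketing fixes (an exact fix hit
    returns that fix); times before the first fix are unresolved.
    """
    t = np.datetime64(t_start, "ns").astype("int64") / 1e9
    pos = _locate_many(traj, np.array([t]), rule="interpolate")
    if np.isnan(pos[0, 0]):
        return None
    return tuple(float(v) for v in pos[0])


def _locate_many(traj: Trajectory, t_sec: np.ndarray,
                 rule: str = "interpolate") -> np.ndarray:
    """Vectorized start location; rows of NaN mark unresolved times."""
    ts = traj.t_seconds
    out = np.full((len(t_sec), 3), np.nan)
    ok = (t_sec >= ts[0]) & (t_sec <= ts[-1])
    if ok.any():
        tq = t_sec[ok]
        if rule == "interpolate":
            out[ok, 0] = np.interp(tq, ts, traj.easting)
            out[ok, 1] = np.interp(tq, ts, traj.northing)
            out[ok, 2] = np.interp(tq, ts, traj.elevation)
        elif rule == "nearest":
            j = np.searchsorted(ts, tq)
            j = np.clip(j, 1, len(ts) - 1)
            left_closer = (tq - ts[j - 1]) <= (ts[j] - tq)
            j = np.where(left_closer, j - 1, j)
            out[ok, 0] = traj.easting[j]
            out[ok, 1] = traj.northing[j]
            out[ok, 2] = traj.elevation[j]
        else:
            raise ValueError(f"unknown start rule {rule!r}")
    return out


def simulate_events(traj: Trajectory, p_samples: np.ndarray,
                    cfg: AnalysisConfig, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, SimulationInfo]:
    """Simulate ``cfg.n_endpoint_draws`` dispersal events for one individual.

    Each event pairs a random endpoint fix with a passage time drawn
    uniformly from ``p_samples``; the ingestion start is located at
    (endpoint time - p). Start times falling before the first fix trigger a
    redraw of the whole (endpoint, p) pair, up to ``cfg.max_redraws``
    rounds; events still unresolved are dropped and counted in the returned
    :class:`SimulationInfo`.
    """
    p_samples = np.asarray(p_samples, dtype=float)
    if p_samples.size == 0:
        raise ValueError("p_samples must be non-empty")
    if len(traj) < 2:
        raise ValueError(f"{traj.animal_id}: trajectory needs >= 2 fixes")
    n = cfg.n_endpoint_draws
    ts = traj.t_seconds

    end_idx = rng.integers(0, len(traj), n)
    p = p_samples[rng.integers(0, p_samples.size, n)]
    t_start = ts[end_idx] - p * 3600.0
    unresolved = t_start < ts[0]
    for _ in range(cfg.max_redraws):
        if not unresolved.any():
            break
        m = int(unresolved.sum())
        end_idx[unresolved] = rng.integers(0, len(traj), m)
        p[unresolved] = p_samples[rng.integers(0, p_samples.size, m)]
        t_start[unresolved] = ts[end_idx[unresolved]] - p[unresolved] * 3600.0
        unresolved = t_start < ts[0]
    keep = ~unresolved
    n_dropped = int(unresolved.sum())
    if n_dropped == n:
        raise ValueError(
            f"{traj.animal_id}: every event start fell before the first fix; "
            "the trajectory is too short for the passage-time distribution")

    end_idx, p, t_start = end_idx[keep], p[keep], t_start[keep]
    start = _locate_many(traj, t_start, rule=cfg.start_rule)
    end_e = traj.easting[end_idx]
    end_n = traj.northing[end_idx]
    end_z = traj.elevation[end_idx]
    months = pd.DatetimeIndex(traj.times[end_idx]).month

    events = pd.DataFrame({
        "animal_id": traj.animal_id,
        "month": months.astype(int),
        "passage_h": p,
        "start_e": start[:, 0], "start_n": start[:, 1], "start_z": start[:, 2],
        "end_e": end_e, "end_n": end_n, "end_z": end_z,
    })
    events["d_horiz_m"] = np.hypot(events["end_e"] - events["start_e"],
                                   events["end_n"] - events["start_n"])
    events["d_vert_m"] = events["end_z"] - events["start_z"]
    info = SimulationInfo(animal_id=traj.animal_id, n_requested=n,
                          n_events=len(events), n_dropped=n_dropped)
    return events, info


def simulate_events_exhaustive(traj: Trajectory, p_values: np.ndarray,
                               cfg: AnalysisConfig) -> pd.DataFrame:
    """Enumerate every (endpoint fix, passage time) pair deterministically.

    The exhaustive mode of the simulator: on small trajectories and discrete
    passage-time sets it produces the full population of events the random
    simulator samples from (unresolved starts are dropped, never redrawn,
    since redrawing cannot change the population).
    """
    p_values = np.asarray(p_values, dtype=float)
    ts = traj.t_seconds
    end_idx = np.repeat(np.arange(len(traj)), p_values.size)
    p = np.tile(p_values, len(traj))
    t_start = ts[end_idx] - p * 3600.0
    keep = t_start >= ts[0]
    end_idx, p, t_start = end_idx[keep], p[keep], t_start[keep]
    start = _locate_many(traj, t_start, rule=cfg.start_rule)
    months = pd.DatetimeIndex(traj.times[end_idx]).month
    events = pd.DataFrame({
        "animal_id": traj.animal_id,
        "month": months.astype(int),
        "passage_h": p,
        "start_e": start[:, 0], "start_n": start[:, 1], "start_z": start[:, 2],
        "end_e": traj.easting[end_idx], "end_n": traj.northing[end_idx],
        "end_z": traj.elevation[end_idx],
    })
    events["d_horiz_m"] = np.hypot(events["end_e"] - events["start_e"],
                                   events["end_n"] - events["start_n"])
    events["d_vert_m"] = events["end_z"] - events["start_z"]
    return events


def ldd_table(events: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Per-(individual, month) long-distance dispersal probabilities.

    ``horizontal`` is the fraction of events with horizontal displacement
    strictly beyond ``cfg.horizontal_threshold``; ``upward``/``downward``
    the fractions beyond +/- ``cfg.vertical_threshold`` in elevation.
    """
    if events.empty:
        raise ValueError("no events")
    flags = events[["animal_id", "month"]].copy()
    flags["horizontal"] = events["d_horiz_m"] > cfg.horizontal_threshold
    flags["upward"] = events["d_vert_m"] > cfg.vertical_threshold
    flags["downward"] = events["d_vert_m"] < -cfg.vertical_threshold
    out = flags.groupby(["animal_id", "month"], sort=True).agg(
        horizontal=("horizontal", "mean"),
        upward=("upward", "mean"),
        downward=("downward", "mean"),
        n_events=("horizontal", "size"),
    ).reset_index()
    return out


def kernel_summary(events: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """Pooled dispersal-kernel summary across all individuals and months."""
    if events.empty:
        raise ValueError("no events")
    dh = events["d_horiz_m"].to_numpy()
    dv = events["d_vert_m"].to_numpy()
    return {
        "n_events": int(len(events)),
        "mean_horizontal_m": float(dh.mean()),
        "frac_horizontal_ldd": float((dh > cfg.horizontal_threshold).mean()),
        "frac_upward_ldd": float((dv > cfg.vertical_threshold).mean()),
        "frac_downward_ldd": float((dv < -cfg.vertical_threshold).mean()),
        "horizontal_q01_m": float(np.quantile(dh, 0.01)),
        "horizontal_q99_m": float(np.quantile(dh, 0.99)),
        "vertical_q01_m": float(np.quantile(dv, 0.01)),
        "vertical_q99_m": float(np.quantile(dv, 0.99)),
    }
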