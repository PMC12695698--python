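"""Trajectory regularization and fine-scale activity estimation.

Position time series are split into sub-trajectories wherever the gap
between consecutive fixes exceeds ``max_gap`` (default 1800 s), linearly
interpolated on a fixed 80-s lattice (the minimum transmitter transmission
delay), and converted to an activity rate in meters per hour:

    activity = dist / dt * 3600

with ``dist`` the Euclidean distance between successive interpolated
positions and ``dt`` the 80-s interpolation period. Steps are labeled day or
night by the sunrise/sunset calendar (label taken at the step start) and
averaged per individual x ISO week x diel period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import DielCalendar

log = logging.getLogger(__name__)

DEFAULT_STEP_S = 80.0
DEFAULT_MAX_GAP_S = 1800.0


@dataclass
class SubTrajectory:
    transmitter_id: str
    fixes: pd.DataFrame  # columns timestamp, x_m, y_m; strictly increasing time

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[-1]


def split_subtrajectories(
    fixes: pd.DataFrame, max_gap: float = DEFAULT_MAX_GAP_S
) -> tuple[list[SubTrajectory], int]:
    """Cut each individual's fix sequence wherever the inter-fix gap exceeds
    ``max_gap`` seconds; segments with fewer than 2 fixes are discarded.

    Returns (sub-trajectories, number of discarded short segments).
    """
    subs: list[SubTrajectory] = []
    n_dropped = 0
    for tid, grp in fixes.groupby("transmitter_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
        dt = grp["timestamp"].diff().dt.total_seconds().to_numpy()
        seg = np.cumsum(np.nan_to_num(dt, nan=0.0) > max_gap)
        for _, part in grp.groupby(seg, sort=True):
            if len(part) < 2:
                n_dropped += 1
                continue
            subs.append(SubTrajectory(str(tid), part.reset_index(drop=True)))
    if n_dropped:
        log.info("discarded %d sub-trajectories with < 2 fixes", n_dropped)
    return subs, n_dropped


def interpolate(sub: SubTrajectory, step: float = DEFAULT_STEP_S) -> pd.DataFrame:
    """Linear interpolation on the lattice t0, t0+step, ... <= t_end.

    Duplicate timestamps are collapsed to their mean position (logged).
    Returns a DataFrame with columns timestamp, x_m, y_m.
    """
    fx = sub.fixes
    t = fx["timestamp"].astype("int64").to_numpy() / 1e9  # epoch seconds
    x = fx["x_m"].to_numpy(float)
    y = fx["y_m"].to_numpy(float)
    if len(np.unique(t)) != len(t):
        log.info("%s: collapsing duplicate timestamps to mean positions", sub.transmitter_id)
        agg = pd.DataFrame({"t": t, "x": x, "y": y}).groupby("t", sort=True).mean()
        t, x, y = agg.index.to_numpy(), agg["x"].to_numpy(), agg["y"].to_numpy()
    if len(t) < 2:
        raise ValueError("need >= 2 distinct fix times to interpolate")
    n_steps = int(np.floor((t[-1] - t[0]) / step))
    tq = t[0] + step * np.arange(n_steps + 1)
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime(tq * 1e9, utc=True),
            "x_m": np.interp(tq, t, x),
            "y_m": np.interp(tq, t, y),
        }
    )


def compute_activity(interp: pd.DataFrame, step: float = DEFAULT_STEP_S) -> pd.DataFrame:
    """Per-step distance and activity (m/h) from interpolated positions.

    Output has one row per consecutive pair: timestamp (step start), dist_m,
    dt_s, activity_mh = dist/dt * 3600.
    """
    if len(interp) < 2:
        raise ValueError("need >= 2 interpolated positions")
    dist = np.hypot(np.diff(interp["x_m"].to_numpy()), np.diff(interp["y_m"].to_numpy()))
    return pd.DataFrame(
        {
            "timestamp": interp["timestamp"].iloc[:-1].to_numpy(),
            "dist_m": dist,
            "dt_s": step,
            "activity_mh": dist / step * 3600.0,
        }
    )


def activity_steps(
    fixes: pd.DataFrame,
    calendar: DielCalendar,
    step: float = DEFAULT_STEP_S,
    max_gap: float = DEFAULT_MAX_GAP_S,
) -> pd.DataFrame:
    """Full per-individual step table: split, interpolate, Eq.-style activity,
    diel label at the step start instant."""
    subs, _ = split_subtrajectories(fixes, max_gap=max_gap)
    frames = []
    for sub in subs:
        interp = interpolate(sub, step=step)
        if len(interp) < 2:
            continue
        steps = compute_activity(interp, step=step)
        steps.insert(0, "transmitter_id", sub.transmitter_id)
        frames.append(steps)
    if not frames:
        return pd.DataFrame(
            columns=["transmitter_id", "timestamp", "dist_m", "dt_s", "activity_mh", "diel"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["diel"] = calendar.label_series(out["timestamp"])
    return out


def aggregate_weekly(steps: pd.DataFrame) -> pd.DataFrame:
    """Mean step activity per (individual, ISO year, ISO week 1-53, diel).

    ISO year is carried so that the same week-of-year in different calendar
    years stays a distinct repeated measure; the week number itself is the
    seasonal covariate used downstream.
    """
    if steps.empty:
        return pd.DataFrame(
            columns=["transmitter_id", "iso_year", "iso_week", "diel", "activity_mh", "n_steps"]
        )
    iso = steps["timestamp"].dt.isocalendar()
    grouped = (
        steps.assign(iso_year=iso["year"].astype(int), iso_week=iso["week"].astype(int))
        .groupby(["transmitter_id", "iso_year", "iso_week", "diel"], sort=True)["activity_mh"]
        .agg(activity_mh="mean", n_steps="size")
        .reset_index()
    )
    return grouped
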