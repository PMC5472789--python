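"""Kinematic preprocessing and behavioural metrics of the reaching task.

The central quantity is the dynamic-time-warping (DTW) deviation of an
individual reach trajectory from the expert reference (the average of 50
random first-success trials from the final session), used both as the
behavioural learning read-out and to select trajectory-matched trials
that control downstream neural analyses for kinematic variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (KinematicTrace, PHASE_TIME_COLUMNS, validate_trial_table)

__all__ = [
    "TrajectoryDeviation", "BehaviorSummary",
    "compute_velocity", "build_reference_trajectory", "dtw_deviation",
    "summarize_behavior", "select_trajectory_matched_trials",
    "extract_trial_traces",
]


def compute_velocity(trace: KinematicTrace) -> np.ndarray:
    """Instantaneous speed (cm/s): centred finite differences of (x, y).

    Endpoints use one-sided differences.  Raises for fewer than two
    samples; non-uniform sampling is rejected at trace construction.
    """
    if trace.n_frames < 2:
        raise ValueError("need >= 2 samples for velocity")
    vx = np.gradient(trace.x, trace.dt)
    vy = np.gradient(trace.y, trace.dt)
    return np.hypot(vx, vy)


def _resample_xy(xy: np.ndarray, n: int) -> np.ndarray:
    """Linear resampling of an (m, 2) path to n points on [0, 1]."""
    m = xy.shape[0]
    if m == n:
        return xy
    u_old = np.linspace(0, 1, m)
    u_new = np.linspace(0, 1, n)
    return np.column_stack([np.interp(u_new, u_old, xy[:, k]) for k in range(2)])


def build_reference_trajectory(trials: list, n: int = 50,
                               seed: int | None = None,
                               frame_rate_hz: float = 80.0) -> KinematicTrace:
    """Expert reference path: the average of ``n`` random eligible trials.

    Trials (KinematicTrace objects) are time-normalized by linear
    resampling to the median trial length, then averaged pointwise.  The
    default ``n=50`` matches the study design (50 random first-success
    trials from the last training session).
    """
    if len(trials) < n:
        raise ValueError(f"need >= {n} eligible trials, got {len(trials)}")
    rng = np.random.default_rng(seed)
    chosen = [trials[i] for i in rng.choice(len(trials), size=n, replace=False)]
    lengths = [t.n_frames for t in chosen]
    target = int(np.median(lengths))
    stack = np.stack([_resample_xy(t.positions(), target) for t in chosen])
    mean_xy = stack.mean(axis=0)
    ts = np.arange(target) / frame_rate_hz
    return KinematicTrace(ts, mean_xy[:, 0], mean_xy[:, 1], frame_rate_hz)


@dataclass
class TrajectoryDeviation:
    """Optimal DTW alignment of one trajectory to the reference."""

    path: np.ndarray          # (L, 2) index pairs into (traj, ref)
    cumulative_distance: float

    def __post_init__(self):
        if self.cumulative_distance < 0:
            raise ValueError("cumulative distance must be >= 0")


def dtw_deviation(traj: KinematicTrace | np.ndarray,
                  ref: KinematicTrace | np.ndarray) -> TrajectoryDeviation:
    """Classical DTW with Euclidean local cost on 2D (or 1D) points.

    Step set {(1,0), (0,1), (1,1)}, no global band.  The cumulative
    distance is the cost of the optimal warping path; the path itself is
    returned as (i, j) index pairs from (0,0) to (n-1, m-1).
    """
    a = traj.positions() if isinstance(traj, KinematicTrace) else np.atleast_2d(
        np.asarray(traj, float).reshape(len(traj), -1))
    b = ref.positions() if isinstance(ref, KinematicTrace) else np.atleast_2d(
        np.asarray(ref, float).reshape(len(ref), -1))
    n, m = a.shape[0], b.shape[0]
    if n == 0 or m == 0:
        raise ValueError("empty input sequence")
    # local cost matrix
    diff = a[:, None, :] - b[None, :, :]
    cost = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        c = cost[i - 1]
        row = acc[i]
        prev = acc[i - 1]
        for j in range(1, m + 1):
            row[j] = c[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    # backtrack
    i, j = n, m
    path = [(n - 1, m - 1)]
    while (i, j) != (1, 1):
        moves = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        vals = [acc[p] for p in moves]
        i, j = moves[int(np.argmin(vals))]
        path.append((i - 1, j - 1))
    path.reverse()
    return TrajectoryDeviation(path=np.array(path),
                               cumulative_distance=float(acc[n, m]))


@dataclass
class BehaviorSummary:
    """Per-session behavioural aggregates."""

    table: pd.DataFrame       # one row per (day, session)
    n_excluded: int = 0

    def conserved_counts(self) -> bool:
        t = self.table
        return bool(np.all(
            t["n_success"] + t["n_failure"] + t["n_other"] == t["n_trials"]))


def summarize_behavior(tt: pd.DataFrame,
                       deviations: pd.DataFrame | None = None) -> BehaviorSummary:
    """Per-session success rate, first-attempt delay, phase durations.

    Phase durations follow the study definitions: extension = orient to
    extend, grasp = extend to grasp, retraction = retract to complete.
    Trials missing any phase timestamp are excluded and counted.
    ``deviations`` may supply a per-trial ``deviation`` column (indexed
    like ``tt``) whose session mean/s.d. is appended.
    """
    if len(tt) == 0:
        raise ValueError("empty trial table")
    validate_trial_table(tt)
    phases = tt[PHASE_TIME_COLUMNS].to_numpy(float)
    ok = np.isfinite(phases).all(axis=1) & np.isfinite(
        tt["food_provided_time"].to_numpy(float))
    n_excluded = int((~ok).sum())
    tt = tt[ok].copy()
    tt["delay"] = tt["orient_time"] - tt["food_provided_time"]
    tt["extension_dur"] = tt["extend_time"] - tt["orient_time"]
    tt["grasp_dur"] = tt["grasp_time"] - tt["extend_time"]
    tt["retraction_dur"] = tt["complete_time"] - tt["retract_time"]
    if deviations is not None:
        tt = tt.join(deviations["deviation"], how="left")

    rows = []
    for (day, sess), grp in tt.groupby(["day", "session"]):
        n = len(grp)
        row = {
            "day": day, "session": sess, "n_trials": n,
            "n_success": int((grp["outcome"] == "first_success").sum()),
            "n_failure": int((grp["outcome"] == "first_failure").sum()),
            "n_other": int((grp["outcome"] == "other").sum()),
            "success_rate_pct": 100.0 * (grp["outcome"] == "first_success").mean(),
            "delay_mean_s": grp["delay"].mean(),
            "delay_sd_s": grp["delay"].std(ddof=1) if n > 1 else 0.0,
        }
        for col in ("extension_dur", "grasp_dur", "retraction_dur"):
            row[f"{col}_mean_s"] = grp[col].mean()
            row[f"{col}_sd_s"] = grp[col].std(ddof=1) if n > 1 else 0.0
        if "deviation" in grp:
            row["deviation_mean"] = grp["deviation"].mean()
            row["deviation_sd"] = grp["deviation"].std(ddof=1) if n > 1 else 0.0
        rows.append(row)
    return BehaviorSummary(table=pd.DataFrame(rows), n_excluded=n_excluded)


def extract_trial_traces(trace: KinematicTrace, tt: pd.DataFrame,
                         start_col: str = "orient_time",
                         stop_col: str = "complete_time",
                         align_origin: bool = False) -> list:
    """Per-trial KinematicTrace slices of a session trace.

    ``align_origin`` subtracts the trial's starting position (spatial
    alignment on the slot) before returning.
    """
    out = []
    for _, row in tt.iterrows():
        seg = trace.slice(float(row[start_col]), float(row[stop_col]))
        if seg.n_frames < 2:
            continue
        if align_origin:
            seg = KinematicTrace(seg.timestamps, seg.x - seg.x[0],
                                 seg.y - seg.y[0], seg.frame_rate_hz)
        out.append(seg)
    return out


def select_trajectory_matched_trials(trials: list, ref: KinematicTrace,
                                     n: int = 30, seed: int | None = None,
                                     deviations: np.ndarray | None = None):
    """Trajectory-matched subset: deviation within mean +/- s.d. of the pool.

    Computes (or accepts precomputed) DTW deviations of each trial from
    the reference, filters trials inside one standard deviation of the
    pool mean, and samples ``n`` of them without replacement with a
    seeded RNG.  Returns ``(indices, deviations)``.
    """
    if deviations is None:
        deviations = np.array([dtw_deviation(t, ref).cumulative_distance
                               for t in trials])
    deviations = np.asarray(deviations, float)
    mu, sd = deviations.mean(), deviations.std(ddof=1) if len(deviations) > 1 else 0.0
    inside = np.flatnonzero((deviations >= mu - sd) & (deviations <= mu + sd))
    if inside.size < n:
        raise ValueError(
            f"trajectory-matched pool has {inside.size} trials, need {n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(inside, size=n, replace=False)
    return np.sort(chosen), deviations
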