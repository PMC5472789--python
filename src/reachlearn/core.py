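"""Shared containers for the pipeline.

Everything downstream consumes three kinds of primary data: spike-time
tables per unit/day/session, 2D forelimb kinematics sampled at the camera
frame rate, and trial-event tables.  These are thin dataclasses around
numpy arrays / pandas frames with the invariants the analyses assume
(sorted times, uniform sampling) checked at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order of a trial table.  Phase times are in seconds on the
#: session clock and must be strictly increasing within a trial.
TRIAL_COLUMNS = [
    "trial", "day", "session", "food_provided_time",
    "orient_time", "advance_time", "extend_time",
    "grasp_time", "retract_time", "complete_time", "outcome",
]

PHASE_TIME_COLUMNS = [
    "orient_time", "advance_time", "extend_time",
    "grasp_time", "retract_time", "complete_time",
]

#: Allowed trial outcomes.
OUTCOMES = ("first_success", "first_failure", "other")


class InsufficientDataError(ValueError):
    """Raised when an analysis has too few spikes/trials to be defined."""


@dataclass
class SpikeTrain:
    """Event times of one sorted unit within one recording span.

    Parameters
    ----------
    unit_id : str
    times : array of float
        Spike times in seconds, sorted ascending.
    t_start, t_stop : float
        Recording span covered by the train (``t_start <= times <= t_stop``).
    day, session : int
        Labels locating the recording within the training schedule.
    """

    unit_id: str
    times: np.ndarray
    t_start: float
    t_stop: float
    day: int = 0
    session: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            self.times = np.sort(self.times)
        if self.t_stop < self.t_start:
            raise ValueError("t_stop < t_start")
        if self.times.size and (
            self.times[0] < self.t_start - 1e-9 or self.times[-1] > self.t_stop + 1e-9
        ):
            raise ValueError("spike times outside [t_start, t_stop]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def rate(self) -> float:
        return self.n_spikes / self.duration if self.duration > 0 else np.nan

    def isi(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times)

    def bin_counts(self, bin_s: float) -> np.ndarray:
        """Spike counts on a uniform grid of width ``bin_s`` over the span."""
        n = int(np.floor(self.duration / bin_s))
        edges = self.t_start + bin_s * np.arange(n + 1)
        return np.histogram(self.times, bins=edges)[0]


@dataclass
class KinematicTrace:
    """2D paw position sampled uniformly at the camera frame rate.

    ``timestamps`` must be strictly increasing and uniformly spaced to
    within 1e-6 s; positions are in cm.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate_hz: float = 80.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.timestamps.shape == self.x.shape == self.y.shape):
            raise ValueError("timestamps/x/y shape mismatch")
        if self.timestamps.size >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValueError("timestamps not strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise ValueError("non-uniform sampling; resample first")

    @property
    def n_frames(self) -> int:
        return int(self.timestamps.size)

    @property
    def dt(self) -> float:
        if self.timestamps.size >= 2:
            return float(self.timestamps[1] - self.timestamps[0])
        return 1.0 / self.frame_rate_hz

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if self.n_frames else 0.0

    def positions(self) -> np.ndarray:
        """(n, 2) array of xy positions."""
        return np.column_stack([self.x, self.y])

    def slice(self, t0: float, t1: float) -> "KinematicTrace":
        m = (self.timestamps >= t0 - 1e-9) & (self.timestamps <= t1 + 1e-9)
        return KinematicTrace(self.timestamps[m], self.x[m], self.y[m],
                              self.frame_rate_hz)


def validate_trial_table(tt: pd.DataFrame) -> pd.DataFrame:
    """Check trial-table invariants: phase times strictly increasing, outcomes known."""
    missing = [c for c in TRIAL_COLUMNS if c not in tt.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    phases = tt[PHASE_TIME_COLUMNS].to_numpy(dtype=float)
    ok = np.isfinite(phases).all(axis=1)
    if np.any(np.diff(phases[ok], axis=1) <= 0):
        raise ValueError("phase times not strictly increasing within a trial")
    bad = set(tt["outcome"]) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcomes: {bad}")
    return tt


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG for a (seed, key...) combination.

    Same seed and key always yield the same stream; distinct keys yield
    independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key)))


def spike_trains_to_frame(trains: list[SpikeTrain]) -> pd.DataFrame:
    """Long-format ``unit_id, day, session, time_s`` table (CSV interface)."""
    rows = []
    for tr in trains:
        rows.append(pd.DataFrame({
            "unit_id": tr.unit_id, "day": tr.day, "session": tr.session,
            "time_s": tr.times,
        }))
    if not rows:
        return pd.DataFrame(columns=["unit_id", "day", "session", "time_s"])
    return pd.concat(rows, ignore_index=True)
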