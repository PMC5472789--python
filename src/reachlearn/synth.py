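"""Synthetic recordings of a skilled forelimb-reaching experiment.

The generator emulates the statistical structure of a 7-day single-pellet
reaching study with chronic extracellular recording: 6 sessions/day of
reaching behaviour whose phase durations, response delay and trajectory
noise shrink with a per-session skill level; three functional classes of
pyramidal neurons (stable movement-coding "type 1", task-recruited
"type 2" with a day-by-day shrinking lag and growing velocity coupling,
and non-coding "type 3") plus fast-spiking interneurons; slowly drifting
spike waveforms; laminar field potentials produced by a known
depth-localized current sink; and a dopamine-depleted scenario in which
skill and the learned type-2 parameters decay overnight.

Every generator is deterministic under ``SimConfig.rng_seed``: the seed
is combined with (day, session, unit) keys so regenerating any part of
the experiment yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.ndimage import gaussian_filter1d

from .core import KinematicTrace, SpikeTrain, spawn_rng, validate_trial_table

__all__ = [
    "SimConfig", "GroundTruth",
    "generate_session_kinematics", "generate_ensemble_spikes",
    "generate_waveform_series", "generate_feature_clusters",
    "generate_laminar_fp",
]


# --------------------------------------------------------------------------
# configuration

def _default_neuron_counts() -> dict:
    # per-class counts of one simulated animal's ensemble
    return {"type1_pn": 4, "type2_pn": 12, "type3_pn": 11, "interneuron": 5}


def _default_baseline_rates() -> dict:
    # spontaneous rates (Hz): stable movement-coding cells fire faster than
    # task-recruited ones; interneurons faster still
    return {"type1_pn": 9.2, "type2_pn": 5.9, "type3_pn": 5.9, "interneuron": 15.0}


@dataclass
class SimConfig:
    """Parameters of the simulated experiment.

    The defaults encode the study conditions the pipeline is meant to
    recover: 7 days x 6 sessions, 80 Hz kinematics, a 2 ms absolute
    refractory period, a type-2 lag schedule shrinking by 84 ms from
    day 1 to day 7 with monotonically growing velocity coupling, and a
    first-success probability rising from 8.7% to 46.6% with skill.
    """

    n_days: int = 7
    n_sessions_per_day: int = 6
    trials_per_session: int = 30
    frame_rate_hz: float = 80.0
    session_rest_s: float = 2.0              # paw-at-rest pad before first trial
    spike_refractory_ms: float = 2.0
    neuron_counts: dict = field(default_factory=_default_neuron_counts)
    type1_lag_ms: float = 150.0
    type2_lag_schedule_ms: np.ndarray | None = None   # per-day, monotone decreasing
    type2_gain_schedule: np.ndarray | None = None     # per-day, monotone increasing
    type1_gain_hz: float = 8.0
    baseline_rate_hz: dict = field(default_factory=_default_baseline_rates)
    skill_schedule: np.ndarray | None = None          # per-session s in [0,1]
    success_rate_range: tuple = (0.087, 0.466)
    delay_range_s: tuple = (0.96, 3.44)
    lesion_mode: bool = False
    lesion_retention: float = 0.25           # overnight fraction retained
    waveform_drift_sd: float = 0.02          # per-day template perturbation scale
    waveform_noise_sd: float = 0.05          # per-event white noise (template units)
    waveform_amp_jitter_sd: float = 0.05     # per-event lognormal amplitude jitter
    waveform_amp_drift_sd: float = 0.02      # per-session amplitude walk (log scale)
    traj_noise_floor_cm: float = 0.02
    traj_noise_scale_cm: float = 0.10        # extra noise at skill 0
    rng_seed: int = 0

    def __post_init__(self):
        if self.type2_lag_schedule_ms is None:
            # day 1 -> day 7 shrink of 84 ms (225 -> 141 ms)
            self.type2_lag_schedule_ms = np.linspace(225.0, 141.0, self.n_days)
        self.type2_lag_schedule_ms = np.asarray(self.type2_lag_schedule_ms, float)
        if self.type2_gain_schedule is None:
            # day-1 coupling weak but nonzero: task-recruited units carry
            # marginal day-1 information (lag estimable, usually below the
            # 5-min significance threshold), growing strong by day 7
            self.type2_gain_schedule = np.linspace(1.0, 8.0, self.n_days)
        self.type2_gain_schedule = np.asarray(self.type2_gain_schedule, float)
        if self.skill_schedule is None:
            self.skill_schedule = self._default_skill()
        self.skill_schedule = np.asarray(self.skill_schedule, float)
        self._validate()

    # -- derived schedules -------------------------------------------------

    def _default_skill(self) -> np.ndarray:
        """Saturating learning curve over all sessions, in [0, 1].

        Most of the gain occurs over the first three days, mirroring the
        levelling-off of success rates and phase durations with training.
        In lesion mode each morning retains only ``lesion_retention`` of
        the previous evening's skill (exact, by construction) while the
        within-day increments stay those of the intact curve.
        """
        k = np.arange(self.n_days * self.n_sessions_per_day, dtype=float)
        tau = len(k) / 3.5
        s = (1.0 - np.exp(-k / tau)) / (1.0 - np.exp(-(len(k) - 1) / tau))
        if not self.lesion_mode:
            return s
        out = np.empty_like(s)
        nps = self.n_sessions_per_day
        inc = np.diff(s, prepend=0.0)
        for d in range(self.n_days):
            lo = d * nps
            start = 0.0 if d == 0 else self.lesion_retention * out[lo - 1]
            out[lo] = start + inc[lo] if d else s[0]
            for j in range(1, nps):
                out[lo + j] = out[lo + j - 1] + inc[lo + j]
        return np.clip(out, 0.0, 1.0)

    def skill(self, day: int, session: int) -> float:
        """Skill level for 0-based (day, session)."""
        return float(self.skill_schedule[day * self.n_sessions_per_day + session])

    def lag_schedule(self, cls: str) -> np.ndarray:
        """Per-day true lag (ms) for a neuron class."""
        if cls == "type1_pn":
            return np.full(self.n_days, self.type1_lag_ms)
        if cls == "type2_pn":
            sched = self.type2_lag_schedule_ms.copy()
            if self.lesion_mode:
                sched = sched[0] + self.lesion_retention * (sched - sched[0])
            return sched
        return np.full(self.n_days, np.nan)

    def gain_schedule(self, cls: str) -> np.ndarray:
        """Per-day velocity-coupling gain (Hz) for a neuron class."""
        if cls == "type1_pn":
            return np.full(self.n_days, self.type1_gain_hz)
        if cls == "type2_pn":
            sched = self.type2_gain_schedule.copy()
            if self.lesion_mode:
                sched = sched[0] + self.lesion_retention * (sched - sched[0])
            return sched
        return np.zeros(self.n_days)

    def unit_classes(self) -> list:
        """(unit_id, class) pairs in a fixed order."""
        out = []
        for cls in ("type1_pn", "type2_pn", "type3_pn", "interneuron"):
            for i in range(int(self.neuron_counts.get(cls, 0))):
                out.append((f"{cls}_{i:02d}", cls))
        return out

    def _validate(self):
        if any(v < 0 for v in self.baseline_rate_hz.values()):
            raise ValueError("baseline rates must be >= 0")
        if np.any(self.skill_schedule < -1e-12) or np.any(self.skill_schedule > 1 + 1e-12):
            raise ValueError("skill_schedule values must lie in [0, 1]")
        if len(self.skill_schedule) != self.n_days * self.n_sessions_per_day:
            raise ValueError("skill_schedule length != n_days * n_sessions_per_day")
        lags = self.type2_lag_schedule_ms
        if np.any(np.abs(lags) > 500):
            raise ValueError("type-2 lags must stay within the +/-500 ms analysis grid")
        if np.any(np.diff(lags) > 1e-9):
            raise ValueError("type2_lag_schedule_ms must be monotone decreasing")
        if np.any(np.diff(self.type2_gain_schedule) < -1e-9):
            raise ValueError("type2_gain_schedule must be monotone increasing")
        if len(lags) != self.n_days or len(self.type2_gain_schedule) != self.n_days:
            raise ValueError("per-day schedules must have n_days entries")


@dataclass
class GroundTruth:
    """Generator-side truth for parameter-recovery tests.

    ``units``: one row per unit (unit_id, cls, is_interneuron, baseline_hz,
    plus per-day true lag/gain columns).  ``trials``: the generated trial
    table(s).  ``csd_profile``: true depth profile used for FP generation
    (filled by :func:`generate_laminar_fp`).
    """

    units: pd.DataFrame
    trials: pd.DataFrame | None = None
    csd_profile: np.ndarray | None = None
    depth_um: np.ndarray | None = None


# --------------------------------------------------------------------------
# kinematics

_SLOT_XY = np.array([0.0, 0.0])       # slit opening (cm)
_PELLET_XY = np.array([1.5, 0.8])     # pellet location (cm)
_REST_XY = np.array([0.0, -2.0])      # paw resting position (cm)
# base (unskilled) gaps between successive phase events, seconds
_BASE_GAPS = np.array([0.20, 0.25, 0.30, 0.35, 0.25])
_MIN_GAP_FRACTION = 0.5               # skilled gaps shrink to this fraction


def _min_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on u in [0, 1]."""
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _reach_path(u: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Smooth out-and-back 2D arc: rest -> target (at u=0.5) -> rest.

    The outward and return limbs bow in opposite lateral directions so the
    loop encloses area, as real reach-grasp-retract paths do.
    """
    phase = np.where(u <= 0.5, _min_jerk(u * 2), _min_jerk((1 - u) * 2))
    base = _REST_XY[None, :] + phase[:, None] * (target - _REST_XY)[None, :]
    bow = 0.4 * np.sin(np.pi * np.clip(u, 0, 1)) * np.where(u <= 0.5, 1.0, -1.0)
    # bow perpendicular to the rest->target chord
    chord = target - _REST_XY
    perp = np.array([-chord[1], chord[0]]) / (np.hypot(*chord) + 1e-12)
    return base + bow[:, None] * perp[None, :]


def generate_session_kinematics(config: SimConfig, day: int, session: int):
    """Simulate one session's continuous 80 Hz paw trace and trial table.

    Parameters are 0-based ``day`` in ``[0, n_days)`` and ``session`` in
    ``[0, n_sessions_per_day)``.  Returns ``(KinematicTrace, TrialTable)``.
    Phase durations, the food-provided -> orient delay, trajectory noise
    and the success probability all follow the session's skill level.
    """
    if not (0 <= day < config.n_days):
        raise IndexError(f"day {day} outside [0, {config.n_days})")
    if not (0 <= session < config.n_sessions_per_day):
        raise IndexError(f"session {session} outside [0, {config.n_sessions_per_day})")
    rng = spawn_rng(config.rng_seed, 1, day, session)
    s = config.skill(day, session)
    fr = config.frame_rate_hz
    dt = 1.0 / fr

    p_lo, p_hi = config.success_rate_range
    p_success = p_lo + (p_hi - p_lo) * s
    d_lo, d_hi = config.delay_range_s
    mean_delay = d_hi - (d_hi - d_lo) * s

    rows = []
    segments = []   # (t_grid, xy) pieces
    t = 0.0

    def _rest_until(t0, t1):
        n = max(int(round((t1 - t0) * fr)), 0)
        if n:
            tg = t0 + dt * np.arange(n)
            segments.append((tg, np.tile(_REST_XY, (n, 1))))
        return t0 + n * dt

    t = _rest_until(t, config.session_rest_s)
    for k in range(config.trials_per_session):
        food_t = t
        delay = max(0.15, mean_delay * rng.lognormal(0.0, 0.15 * (1 - s) + 0.02))
        # delay period: paw at rest
        t = _rest_until(t, t + delay)
        orient_t = t
        gaps = _BASE_GAPS * (1.0 - (1.0 - _MIN_GAP_FRACTION) * s)
        gaps = gaps * rng.lognormal(0.0, 0.10 * (1 - s), gaps.size)
        phase_times = orient_t + np.concatenate([[0.0], np.cumsum(gaps)])
        success = rng.random() < p_success
        target = _PELLET_XY.copy()
        if not success:
            # missed grasp: terminal positional offset at the pellet
            target = target + rng.normal(0.0, 0.1, 2) + np.array([0.35, -0.25])
        reach_dur = phase_times[-1] - orient_t
        n = max(int(round(reach_dur * fr)), 2)
        u = np.arange(n) / (n - 1)
        xy = _reach_path(u, target)
        noise_sd = config.traj_noise_floor_cm + config.traj_noise_scale_cm * (1 - s)
        noise = gaussian_filter1d(rng.normal(0, 1.0, (n, 2)), 3.0, axis=0, mode="wrap")
        noise /= max(noise.std(), 1e-9)
        xy = xy + noise_sd * noise
        tg = orient_t + dt * np.arange(n)
        segments.append((tg, xy))
        t = orient_t + n * dt
        # consumption / reset interval
        t = _rest_until(t, t + 1.5)
        rows.append({
            "trial": k, "day": day, "session": session,
            "food_provided_time": food_t,
            "orient_time": phase_times[0], "advance_time": phase_times[1],
            "extend_time": phase_times[2], "grasp_time": phase_times[3],
            "retract_time": phase_times[4], "complete_time": phase_times[5],
            "outcome": "first_success" if success else "first_failure",
        })

    if segments:
        ts = np.concatenate([g for g, _ in segments])
        xy = np.concatenate([p for _, p in segments], axis=0)
    else:
        ts = np.zeros(0)
        xy = np.zeros((0, 2))
    # snap to an exactly uniform grid (float accumulation guard)
    ts = ts[0] + dt * np.arange(len(ts)) if len(ts) else ts
    trace = KinematicTrace(ts, xy[:, 0], xy[:, 1], fr)
    table = pd.DataFrame(rows)
    if len(table):
        validate_trial_table(table)
    return trace, table


# --------------------------------------------------------------------------
# spikes

def _speed(trace: KinematicTrace) -> np.ndarray:
    """Centred-difference speed (cm/s) on the trace's frame grid."""
    if trace.n_frames < 2:
        return np.zeros(trace.n_frames)
    vx = np.gradient(trace.x, trace.dt)
    vy = np.gradient(trace.y, trace.dt)
    return np.hypot(vx, vy)


def ground_truth_units(config: SimConfig) -> pd.DataFrame:
    """Per-unit truth table: class, baseline, per-day lag and gain."""
    rows = []
    for uid, cls in config.unit_classes():
        lag = config.lag_schedule(cls)
        gain = config.gain_schedule(cls)
        row = {
            "unit_id": uid, "cls": cls,
            "is_interneuron": cls == "interneuron",
            "baseline_hz": config.baseline_rate_hz[cls],
        }
        for d in range(config.n_days):
            row[f"lag_ms_day{d}"] = lag[d]
            row[f"gain_hz_day{d}"] = gain[d]
        rows.append(row)
    return pd.DataFrame(rows)


def generate_ensemble_spikes(config: SimConfig, kinematics: KinematicTrace,
                             day: int, session: int = 0):
    """Inhomogeneous-Poisson spike trains coupled to forelimb speed.

    Each unit fires at ``lambda(t) = baseline + gain_day * g(v(t + lag_day))``
    where ``g`` is speed rectified and normalized to the session maximum
    (zero for type-3 units), realized by thinning a homogeneous process and
    enforcing an absolute refractory period by deleting any spike closer
    than ``spike_refractory_ms`` to the previously kept one.

    Returns ``(list[SpikeTrain], GroundTruth)``.
    """
    if not (0 <= day < config.n_days):
        raise IndexError(f"day {day} outside [0, {config.n_days})")
    units = ground_truth_units(config)
    t0 = float(kinematics.timestamps[0]) if kinematics.n_frames else 0.0
    t1 = float(kinematics.timestamps[-1]) if kinematics.n_frames else 0.0
    speed = _speed(kinematics)
    # rectified-linear link of speed; the normalization scale is the 95th
    # percentile (robust to single-frame noise spikes), clipped at 1
    vscale = np.quantile(speed, 0.95) if speed.size else 0.0
    g_norm = (np.clip(speed, 0.0, None) / vscale).clip(max=1.0) \
        if vscale > 0 else np.zeros_like(speed)

    trains = []
    for j, row in units.iterrows():
        rng = spawn_rng(config.rng_seed, 2, day, session, j)
        base = row["baseline_hz"]
        gain = row[f"gain_hz_day{day}"]
        lag_s = row[f"lag_ms_day{day}"] / 1000.0
        dur = t1 - t0
        if dur <= 0:
            trains.append(SpikeTrain(row["unit_id"], np.zeros(0), t0, t0,
                                     day=day, session=session))
            continue
        lam_max = base + max(gain, 0.0) + 1e-12
        n_cand = rng.poisson(lam_max * dur)
        cand = np.sort(rng.uniform(t0, t1, n_cand))
        if gain > 0 and not np.isnan(lag_s):
            # firing at t follows speed at t + lag (firing precedes movement)
            gt = np.interp(cand + lag_s, kinematics.timestamps, g_norm,
                           left=0.0, right=0.0)
            lam = base + gain * gt
        else:
            lam = np.full(cand.shape, base)
        keep = rng.random(n_cand) < lam / lam_max
        times = cand[keep]
        # absolute refractory period by deletion
        if times.size:
            refr = config.spike_refractory_ms / 1000.0
            kept = [times[0]]
            for tt in times[1:]:
                if tt - kept[-1] > refr:
                    kept.append(tt)
            times = np.array(kept)
        trains.append(SpikeTrain(row["unit_id"], times, t0, t1,
                                 day=day, session=session))
    return trains, GroundTruth(units=units)


# --------------------------------------------------------------------------
# waveforms

N_WAVEFORM_SAMPLES = 32
WAVEFORM_FS_HZ = 40_000.0


def _unit_template(config: SimConfig, unit_index: int, cls: str) -> np.ndarray:
    """Two-Gaussian biphasic spike template, 32 samples at 40 kHz.

    Interneurons get narrow waveforms (small valley-to-peak width) and a
    larger valley/peak ratio, pyramidal cells broad ones.
    """
    rng = spawn_rng(config.rng_seed, 3, unit_index)
    t = np.arange(N_WAVEFORM_SAMPLES) / WAVEFORM_FS_HZ * 1000.0  # ms
    if cls == "interneuron":
        w1, sep, ratio = 0.06, 0.18, 0.35
    else:
        w1, sep, ratio = 0.10, 0.40, 0.55
    w1 *= rng.uniform(0.65, 1.45)
    sep *= rng.uniform(0.65, 1.45)
    ratio *= rng.uniform(0.6, 1.4)
    t_valley = 0.25 + rng.uniform(-0.06, 0.06)
    amp = rng.uniform(80.0, 160.0)  # uV
    wf = (-np.exp(-0.5 * ((t - t_valley) / w1) ** 2)
          + ratio * np.exp(-0.5 * ((t - t_valley - sep) / (1.6 * w1)) ** 2))
    return amp * wf


def generate_waveform_series(config: SimConfig, trains: list,
                             unstable_ids: set | None = None,
                             morph_fraction: float = 0.5):
    """Per-event spike waveforms for each train, with slow cross-day drift.

    Returns a list of ``quality.WaveformSet`` (one per train, aligned with
    the input list).  Stable units drift by ``waveform_drift_sd`` (fraction
    of amplitude) per day; units named in ``unstable_ids`` have their
    template morphed toward a different shape by ``morph_fraction`` per day
    elapsed, emulating a lost/exchanged unit.
    """
    from .quality import WaveformSet  # local import to avoid cycle

    unstable_ids = unstable_ids or set()
    uid_index = {uid: i for i, (uid, _) in enumerate(config.unit_classes())}
    classes = dict(config.unit_classes())
    out = []
    for tr in trains:
        idx = uid_index.get(tr.unit_id, abs(hash(tr.unit_id)) % 10_000)
        cls = classes.get(tr.unit_id, "type3_pn")
        template = _unit_template(config, idx, cls)
        amp = np.abs(template).max()
        rng = spawn_rng(config.rng_seed, 4, idx, tr.day, tr.session)
        # cumulative smooth drift over days (deterministic per unit/day)
        drift = np.zeros(N_WAVEFORM_SAMPLES)
        for d in range(tr.day + 1):
            drng = spawn_rng(config.rng_seed, 5, idx, d)
            drift = drift + gaussian_filter1d(
                drng.normal(0.0, 1.0, N_WAVEFORM_SAMPLES), 2.0)
        drift *= config.waveform_drift_sd * amp / max(np.abs(drift).max(), 1e-9) \
            if tr.day >= 0 and config.waveform_drift_sd > 0 else 0.0
        shape = template + drift
        # session-to-session amplitude random walk (electrode-to-soma
        # distance fluctuation): shape is preserved, peak-to-peak is not
        step_index = tr.day * config.n_sessions_per_day + tr.session
        if config.waveform_amp_drift_sd > 0 and step_index > 0:
            steps = [spawn_rng(config.rng_seed, 6, idx, k).normal(
                0.0, config.waveform_amp_drift_sd)
                for k in range(1, step_index + 1)]
            shape = shape * float(np.exp(np.sum(steps)))
        if tr.unit_id in unstable_ids and tr.day > 0:
            other = _unit_template(config, idx + 7919, cls)
            f = min(1.0, morph_fraction * tr.day)
            shape = (1 - f) * shape + f * other
        n_ev = max(tr.n_spikes, 1)
        amps = rng.lognormal(0.0, config.waveform_amp_jitter_sd, n_ev) \
            if config.waveform_amp_jitter_sd > 0 else np.ones(n_ev)
        noise = rng.normal(0.0, config.waveform_noise_sd * amp,
                           (n_ev, N_WAVEFORM_SAMPLES))
        events = amps[:, None] * shape[None, :] + noise
        out.append(WaveformSet(unit_id=tr.unit_id, day=tr.day, events=events,
                               sampling_rate=WAVEFORM_FS_HZ,
                               noise_amplitude=2.0 * config.waveform_noise_sd * amp))
    return out


# --------------------------------------------------------------------------
# feature-space clusters (fixtures for the quality metrics)

def generate_feature_clusters(means, covs, sizes, noise_mean=None,
                              noise_cov=None, n_noise=0, seed=0):
    """Gaussian point clouds in feature space, with an optional noise cloud.

    Returns ``(points, labels)`` where noise points carry label ``-1``.
    Raises ``ValueError`` for singular requested covariances or fewer than
    two clusters.
    """
    means = [np.atleast_1d(np.asarray(m, float)) for m in means]
    if len(means) < 2 and n_noise == 0:
        raise ValueError("need at least 2 clusters (or a noise cloud)")
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for k, (m, c, n) in enumerate(zip(means, covs, sizes)):
        c = np.atleast_2d(np.asarray(c, float))
        if np.linalg.det(c) <= 0:
            raise ValueError(f"cluster {k}: requested covariance is singular")
        pts.append(rng.multivariate_normal(m, c, int(n)))
        labels.append(np.full(int(n), k))
    if n_noise:
        nm = means[0] if noise_mean is None else np.asarray(noise_mean, float)
        nc = np.atleast_2d(covs[0] if noise_cov is None else np.asarray(noise_cov, float))
        if np.linalg.det(nc) <= 0:
            raise ValueError("noise covariance is singular")
        pts.append(rng.multivariate_normal(nm, nc, int(n_noise)))
        labels.append(np.full(int(n_noise), -1))
    return np.concatenate(pts, axis=0), np.concatenate(labels)


# --------------------------------------------------------------------------
# latent population activity (fixtures for the factor-model diagnostics)

def generate_latent_population_counts(config: SimConfig, day: int,
                                      n_trials: int = 30, n_units: int = 12,
                                      n_bins: int = 160, bin_s: float = 0.01,
                                      outcome: str = "first_success",
                                      n_latents: int = 1,
                                      base_latent_sd: float = 1.0,
                                      obs_noise_sd: float = 0.15,
                                      seed_key: int = 0):
    """Trial population counts driven by a low-dimensional latent state.

    Each trial's latent path is a shared smooth mean trajectory (a reach-
    locked excursion) plus across-trial latent noise whose standard
    deviation shrinks with the session's skill level for success trials
    — emulating the consolidation of reproducible population dynamics —
    and stays at the day-1 level for failure trials (schedule-independent
    by construction).  Counts are the squared linear readout, matching
    the square-root transform the factor model applies.

    Returns ``(counts, true_noise_sd)`` with counts (trials, units, bins).
    """
    if not (0 <= day < config.n_days):
        raise IndexError(f"day {day} outside [0, {config.n_days})")
    rng = spawn_rng(config.rng_seed, 7, day, seed_key,
                    0 if outcome == "first_success" else 1)
    s = config.skill(day, config.n_sessions_per_day - 1)
    if outcome == "first_success":
        noise_sd = base_latent_sd * (1.0 - 0.8 * s)
    else:
        noise_sd = base_latent_sd
    t = np.arange(n_bins) * bin_s
    t_mid = t[n_bins // 2]
    mean_path = 3.0 * np.exp(-0.5 * ((t - t_mid) / 0.15) ** 2)
    structure_rng = spawn_rng(config.rng_seed, 8)
    loading = structure_rng.normal(0.0, 0.3, (n_units, n_latents))
    offset = structure_rng.uniform(0.8, 1.4, n_units)
    lat = mean_path[None, None, :] + gaussian_filter1d(
        rng.normal(0.0, 1.0, (n_trials, n_latents, n_bins)), 8.0,
        axis=-1) * noise_sd / gaussian_filter1d(
            np.random.default_rng(0).normal(0, 1, 10000), 8.0).std()
    y = (np.einsum("uk,nkt->nut", loading, lat)
         + offset[None, :, None]
         + rng.normal(0.0, obs_noise_sd, (n_trials, n_units, n_bins)))
    counts = np.clip(y, 0.0, None) ** 2
    return counts, noise_sd


# --------------------------------------------------------------------------
# laminar field potentials

def _alpha_kernel(t: np.ndarray, onset: float, tau: float) -> np.ndarray:
    """Unit-peak alpha-function time course starting at ``onset`` (s)."""
    u = np.clip(t - onset, 0.0, None) / tau
    return u * np.exp(1.0 - u)


def balanced_sink_profile(depth_um: np.ndarray, sink_depth_um: float = 1500.0,
                          sink_width_um: float = 150.0,
                          source_offset_um: float = 350.0,
                          amplitude: float = 1.0) -> np.ndarray:
    """Gaussian current sink flanked by two sources, balanced to sum ~ 0.

    Sink is negative (inward current) at the target depth; flanking source
    amplitudes are scaled so the depth integral vanishes exactly.
    """
    z = np.asarray(depth_um, float)
    sink = -np.exp(-0.5 * ((z - sink_depth_um) / sink_width_um) ** 2)
    src = (np.exp(-0.5 * ((z - sink_depth_um - source_offset_um) / sink_width_um) ** 2)
           + np.exp(-0.5 * ((z - sink_depth_um + source_offset_um) / sink_width_um) ** 2))
    tot_src = src.sum()
    if tot_src > 0 and sink.sum() != 0:
        src = src * (-sink.sum() / tot_src)
    return amplitude * (sink + src)


def generate_laminar_fp(config: SimConfig, n_channels: int = 20,
                        spacing_um: float = 100.0, fs_hz: float = 1000.0,
                        duration_s: float = 0.1, stim_onset_s: float = 0.02,
                        sink_amplitude: float = 1.0, noise_sd_mv: float = 0.0,
                        sigma_s_per_m: float = 0.3,
                        csd_profile: np.ndarray | None = None, seed=None):
    """Evoked laminar field potentials from a known depth current profile.

    A balanced depth profile ``C(z)`` (Gaussian sink at the deep-layer
    depth flanked by sources) with an alpha-function time course drives
    the 1D Poisson relation ``sigma * d2(phi)/dz2 = -C``; the potential is
    obtained by solving the discrete relation on the channel grid with
    grounded virtual channels beyond both ends.  Returns
    ``(fp.LaminarFP, true_profile)``.

    If a caller supplies an unbalanced ``csd_profile`` a warning string is
    recorded in the output metadata rather than raising.
    """
    from .fp import LaminarFP  # local import to avoid cycle

    if n_channels < 3:
        raise ValueError("need >= 3 channels")
    if spacing_um <= 0:
        raise ValueError("spacing must be > 0")
    depth = 200.0 + spacing_um * np.arange(n_channels)  # probe tip span
    if csd_profile is None:
        profile = balanced_sink_profile(depth, amplitude=sink_amplitude)
    else:
        profile = np.asarray(csd_profile, float)
        if profile.shape != (n_channels,):
            raise ValueError("csd_profile length must equal n_channels")
    meta = {}
    h_m = spacing_um * 1e-6
    total = np.abs(profile).sum()
    if total > 0 and abs(profile.sum()) > 0.01 * total:
        meta["warning"] = "requested CSD profile is not balanced (sum C*dz != 0)"

    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    kern = _alpha_kernel(t, stim_onset_s, 0.005)
    c_zt = profile[:, None] * kern[None, :]            # (channels, time)

    # discrete Poisson solve: phi'' = -C/sigma, Dirichlet 0 at virtual ends
    n = n_channels
    ab = np.zeros((3, n))
    ab[0, 1:] = 1.0
    ab[1, :] = -2.0
    ab[2, :-1] = 1.0
    rhs = -c_zt / sigma_s_per_m * h_m**2
    phi = solve_banded((1, 1), ab, rhs)                # (channels, time), V-scale
    phi_mv = phi * 1e3
    if noise_sd_mv > 0:
        rng = np.random.default_rng(config.rng_seed if seed is None else seed)
        phi_mv = phi_mv + rng.normal(0.0, noise_sd_mv, phi_mv.shape)
    lam = LaminarFP(sweeps=phi_mv[None, :, :], depths_um=depth, fs_hz=fs_hz,
                    stim_onset_index=int(round(stim_onset_s * fs_hz)),
                    sigma_s_per_m=sigma_s_per_m, metadata=meta)
    return lam, profile
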