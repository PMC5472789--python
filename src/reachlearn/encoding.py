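"""Single-neuron task correlates and movement-information statistics.

The pivotal statistic is the time-lagged mutual information I(tau)
between a unit's binned spike counts and forelimb speed: spike counts on
a 12.5 ms grid are paired with speed shifted by tau (positive tau =
firing precedes movement), speed is reduced to quantile bins, and the
plug-in MI in bits is evaluated on the lag grid -500..+500 ms in 12.5 ms
steps (81 lags).  I_M is the maximum over the grid and tau_opt its
argmax.  Significance comes from a bootstrap null that resamples the
spike-count bins with replacement, destroying the temporal pairing while
preserving the count marginal, and recomputing I_M per resample; the
observed I_M is called significant when it exceeds the null's 99th
percentile.

The module also provides peri-event histograms with a bootstrap
time-until-divergence read-out, the DTW-warp-controlled re-computation
of I(tau), waveform-based pyramidal/interneuron separation, functional
typing of pyramidal cells from their 7-day I_M vectors (Ward linkage +
Calinski-Harabasz), and the mean-matched Fano factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .core import InsufficientDataError, SpikeTrain

__all__ = [
    "PETH", "MIProfile", "FanoResult", "TypeLabels",
    "compute_peth", "time_until_divergence", "time_lagged_mi",
    "mi_significance", "warp_controlled_mi", "classify_pn_in",
    "cluster_im_types", "mean_matched_fano", "sliding_spike_counts",
    "binned_mi_profile",
]

BIN_S = 0.0125                      # 12.5 ms analysis bin
LAG_GRID_MS = np.arange(-500.0, 500.0 + 1e-9, 12.5)   # 81 lags
N_VELOCITY_BINS = 8
MAX_COUNT_LEVELS = 8


# --------------------------------------------------------------------------
# PETH and time-until-divergence

_SMOOTH_KERNEL = np.exp(-0.5 * (np.arange(-2, 3) / 1.0) ** 2)
_SMOOTH_KERNEL = _SMOOTH_KERNEL / _SMOOTH_KERNEL.sum()   # 5-point Gaussian


@dataclass
class PETH:
    """Peri-event time histogram on the 12.5 ms grid."""

    bin_centers_s: np.ndarray
    counts: np.ndarray                 # (trials, bins)
    z: np.ndarray                      # smoothed z-scored trial average
    alignment: str
    baseline_window_s: tuple
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]


def compute_peth(spikes: SpikeTrain, events: np.ndarray,
                 window: tuple = (-6.0, 1.0),
                 baseline_window: tuple = (-6.0, -4.0),
                 alignment: str = "orient") -> PETH:
    """Trial-aligned binned firing around a behavioural event.

    Counts per 12.5 ms bin per trial; the trial average is smoothed with
    a 5-point Gaussian kernel (sigma = 1 bin) and z-scored against the
    pre-trial baseline window.  Events whose window exceeds the recording
    span are dropped (counted in ``n_dropped``).
    """
    events = np.atleast_1d(np.asarray(events, float))
    if events.size < 1:
        raise ValueError("need >= 1 event")
    lo, hi = window
    n_bins = int(round((hi - lo) / BIN_S))
    edges = lo + BIN_S * np.arange(n_bins + 1)
    centers = edges[:-1] + BIN_S / 2
    rows, dropped = [], 0
    for ev in events:
        if ev + lo < spikes.t_start - 1e-9 or ev + hi > spikes.t_stop + 1e-9:
            dropped += 1
            continue
        rows.append(np.histogram(spikes.times - ev, bins=edges)[0])
    if not rows:
        raise InsufficientDataError("all event windows fall outside the recording")
    counts = np.array(rows)
    avg = counts.mean(axis=0) / BIN_S
    sm = np.convolve(avg, _SMOOTH_KERNEL, mode="same")
    bl = (centers >= baseline_window[0]) & (centers < baseline_window[1])
    mu, sd = sm[bl].mean(), sm[bl].std(ddof=1)
    z = (sm - mu) / sd if sd > 0 else np.full_like(sm, np.nan)
    return PETH(bin_centers_s=centers, counts=counts, z=z, alignment=alignment,
                baseline_window_s=baseline_window, n_dropped=dropped)


def time_until_divergence(peth: PETH, alpha: float = 0.01, run: int = 5,
                          n_boot: int = 1000, seed: int | None = None):
    """First bin starting a run of >= ``run`` bins diverging from baseline.

    Each bin's across-trial mean count is compared (two-sided) against a
    bootstrap distribution of baseline-bin means; the time of the first
    bin opening a run of at least ``run`` bins with p < alpha is
    returned, or None when firing never diverges.
    """
    if peth.n_trials < 10:
        raise InsufficientDataError("need >= 10 trials for divergence bootstrap")
    rng = np.random.default_rng(seed)
    bl_mask = (peth.bin_centers_s >= peth.baseline_window_s[0]) \
        & (peth.bin_centers_s < peth.baseline_window_s[1])
    pool = peth.counts[:, bl_mask].ravel()
    n_tr = peth.n_trials
    boot = rng.choice(pool, size=(n_boot, n_tr), replace=True).mean(axis=1)
    obs = peth.counts.mean(axis=0)
    # two-sided exceedance p-value per bin
    hi = (boot[None, :] >= obs[:, None]).mean(axis=1)
    lo = (boot[None, :] <= obs[:, None]).mean(axis=1)
    p = np.minimum(1.0, 2.0 * np.minimum(hi, lo) + 1.0 / n_boot)
    sig = p < alpha
    count = 0
    for i, s in enumerate(sig):
        count = count + 1 if s else 0
        if count >= run:
            return float(peth.bin_centers_s[i - run + 1])
    return None


# --------------------------------------------------------------------------
# time-lagged mutual information

@dataclass
class MIProfile:
    """I(tau) on the lag grid with its maximum and significance record."""

    lags_ms: np.ndarray
    mi_bits: np.ndarray
    i_m: float
    tau_opt_ms: float
    null_quantiles: dict = field(default_factory=dict)
    threshold: float = np.nan
    p_value: float = np.nan
    significant: bool = False
    degenerate: bool = False

    def __post_init__(self):
        if np.any(self.mi_bits < -1e-12):
            raise ValueError("MI must be nonnegative")


def _plug_in_mi_bits(joint: np.ndarray) -> float:
    """Plug-in MI (bits) from a joint count table."""
    n = joint.sum()
    if n == 0:
        return 0.0
    pj = joint / n
    px = pj.sum(axis=1, keepdims=True)
    py = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    return float(np.sum(pj[nz] * np.log2(pj[nz] / (px @ py)[nz])))


def _discretize_velocity(v: np.ndarray, n_bins: int = N_VELOCITY_BINS):
    """Quantile-bin a velocity series; returns (codes, degenerate flag)."""
    v = np.asarray(v, float)
    if np.ptp(v) == 0 or v.size == 0:
        return np.zeros(v.size, dtype=np.int64), True
    qs = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    codes = np.searchsorted(qs, v, side="right")
    if np.unique(codes).size < 2:
        return codes, True
    return codes, False


def binned_mi_profile(counts: np.ndarray, vel_codes: np.ndarray,
                      lags_ms: np.ndarray = LAG_GRID_MS,
                      bin_s: float = BIN_S,
                      max_count_levels: int = MAX_COUNT_LEVELS) -> np.ndarray:
    """I(tau) between binned counts and discretized velocity.

    Positive tau pairs the count at bin t with velocity at bin
    t + tau/bin: firing preceding movement.
    """
    c = np.clip(np.asarray(counts, np.int64), 0, max_count_levels - 1)
    vb = np.asarray(vel_codes, np.int64)
    t = min(c.size, vb.size)
    c, vb = c[:t], vb[:t]
    kc = int(c.max()) + 1 if c.size else 1
    kv = int(vb.max()) + 1 if vb.size else 1
    shifts = np.round(np.asarray(lags_ms) / (bin_s * 1000.0)).astype(int)
    out = np.empty(shifts.size)
    for i, k in enumerate(shifts):
        if k >= 0:
            a, b = c[:t - k] if k else c, vb[k:]
        else:
            a, b = c[-k:], vb[:t + k]
        if a.size == 0:
            out[i] = 0.0
            continue
        joint = np.bincount(a * kv + b, minlength=kc * kv).reshape(kc, kv)
        out[i] = _plug_in_mi_bits(joint)
    return out


def _bin_series(spikes: SpikeTrain, velocity: np.ndarray,
                vel_times: np.ndarray | None):
    """Common 12.5 ms binning of a train and a velocity series."""
    counts = spikes.bin_counts(BIN_S)
    n = counts.size
    centers = spikes.t_start + BIN_S * (np.arange(n) + 0.5)
    v = np.asarray(velocity, float)
    if vel_times is not None:
        v = np.interp(centers, np.asarray(vel_times, float), v)
    else:
        m = min(n, v.size)
        counts, v, centers = counts[:m], v[:m], centers[:m]
    return counts, v


def time_lagged_mi(spikes: SpikeTrain, velocity: np.ndarray,
                   vel_times: np.ndarray | None = None,
                   lags_ms: np.ndarray = LAG_GRID_MS,
                   n_velocity_bins: int = N_VELOCITY_BINS,
                   min_span_s: float = 60.0) -> MIProfile:
    """Full time-lagged MI profile of one unit against forelimb speed.

    ``velocity`` is the speed series; if sampled on a different grid,
    pass its ``vel_times`` and it is interpolated to the spike-count bin
    centres (at the 80 Hz frame rate the two grids coincide).  Constant
    velocity returns an all-zero profile flagged degenerate.
    """
    if spikes.duration < min_span_s:
        raise InsufficientDataError(
            f"overlapping span {spikes.duration:.1f}s < {min_span_s}s")
    counts, v = _bin_series(spikes, velocity, vel_times)
    codes, degenerate = _discretize_velocity(v, n_velocity_bins)
    lags_ms = np.asarray(lags_ms, float)
    if degenerate:
        mi = np.zeros(lags_ms.size)
    else:
        mi = binned_mi_profile(counts, codes, lags_ms)
    i_best = int(np.argmax(mi))
    return MIProfile(lags_ms=lags_ms, mi_bits=mi, i_m=float(mi[i_best]),
                     tau_opt_ms=float(lags_ms[i_best]), degenerate=degenerate)


# ---- bootstrap null (numba kernel) ----------------------------------------

@njit(cache=True)
def _null_im_kernel(nz_val, t_len, vb, vb_hists, shifts, win_lo, win_hi,
                    kc, kv, n_boot, seed):   # pragma: no cover - jitted
    """Null I_M samples under bin-resampling of the spike counts.

    Each resample redraws all T count bins iid from the count marginal
    (``nz_val`` holds the values of the original nonzero bins, so a slot
    becomes nonzero with probability n_nz/T and then takes a value drawn
    from the nonzero marginal).  Only resampled nonzero bins — a sparse
    set — need explicit pairing with the velocity codes; the zero-count
    row of each joint table follows from the precomputed per-lag velocity
    histograms ``vb_hists`` over the valid windows [win_lo, win_hi).
    """
    np.random.seed(seed)
    n_nz = nz_val.shape[0]
    n_lags = shifts.shape[0]
    out = np.empty(n_boot)
    p_nz = n_nz / t_len
    log2 = np.log(2.0)
    pos = np.empty(t_len, np.int64)
    val = np.empty(t_len, np.int64)
    pool = np.arange(t_len)
    for r in range(n_boot):
        # the resampled series is nonzero in Binomial(T, p_nz) distinct
        # slots; draw them by partial Fisher-Yates (the pool stays a
        # permutation across replicates, so no reset is needed)
        m = np.random.binomial(t_len, p_nz)
        for i in range(m):
            j = i + np.random.randint(0, t_len - i)
            tmp = pool[i]
            pool[i] = pool[j]
            pool[j] = tmp
            pos[i] = pool[i]
            val[i] = nz_val[np.random.randint(0, n_nz)]
        best = 0.0
        for li in range(n_lags):
            lo = win_lo[li]
            hi = win_hi[li]
            length = hi - lo
            if length <= 0:
                continue
            k = shifts[li]
            joint = np.zeros((kc, kv))
            for i in range(m):
                t = pos[i]
                if lo <= t < hi:
                    joint[val[i], vb[t + k]] += 1.0
            # fill zero-count row from the window's velocity histogram
            for j in range(kv):
                tot = vb_hists[li, j]
                s = 0.0
                for a in range(1, kc):
                    s += joint[a, j]
                joint[0, j] = tot - s
            # plug-in MI in bits
            n = float(length)
            mi = 0.0
            for a in range(kc):
                pa = 0.0
                for j in range(kv):
                    pa += joint[a, j]
                if pa == 0.0:
                    continue
                for j in range(kv):
                    pj = joint[a, j]
                    if pj <= 0.0:
                        continue
                    pb = vb_hists[li, j]
                    if pb > 0.0:
                        mi += (pj / n) * np.log((pj * n) / (pa * pb)) / log2
            if mi > best:
                best = mi
        out[r] = best
    return out


def mi_significance(spikes: SpikeTrain, velocity: np.ndarray,
                    vel_times: np.ndarray | None = None,
                    n_boot: int = 2000, lags_ms: np.ndarray = LAG_GRID_MS,
                    n_velocity_bins: int = N_VELOCITY_BINS,
                    seed: int = 0, null_method: str = "resample",
                    min_span_s: float = 60.0):
    """Bootstrap significance of I_M against a pairing-destroyed null.

    The null resamples the spike-count bins with replacement (preserving
    the count marginal, destroying temporal pairing) and recomputes I_M
    over the full lag grid per resample.  Returns an ``MIProfile`` whose
    ``threshold`` is the null's 99th percentile and ``p_value`` the null
    exceedance fraction of the observed I_M.  ``null_method='circular'``
    instead rotates the count series by a random offset per resample.
    """
    if n_boot < 200:
        raise ValueError("n_boot < 200: the 99th-percentile estimate is unstable")
    prof = time_lagged_mi(spikes, velocity, vel_times, lags_ms,
                          n_velocity_bins, min_span_s=min_span_s)
    counts, v = _bin_series(spikes, velocity, vel_times)
    codes, degenerate = _discretize_velocity(v, n_velocity_bins)
    if degenerate:
        prof.threshold = 0.0
        prof.p_value = 1.0
        return prof
    c = np.clip(counts.astype(np.int64), 0, MAX_COUNT_LEVELS - 1)
    t_len = min(c.size, codes.size)
    c, vb = c[:t_len], codes[:t_len].astype(np.int64)
    kc = int(c.max()) + 1
    kv = int(vb.max()) + 1
    shifts = np.round(np.asarray(lags_ms) / (BIN_S * 1000.0)).astype(np.int64)
    win_lo = np.where(shifts >= 0, 0, -shifts).astype(np.int64)
    win_hi = np.where(shifts >= 0, t_len - shifts, t_len).astype(np.int64)
    vb_hists = np.zeros((shifts.size, kv))
    for i, k in enumerate(shifts):
        seg = vb[win_lo[i] + k: win_hi[i] + k]
        vb_hists[i] = np.bincount(seg, minlength=kv)

    rng = np.random.default_rng(seed)
    if null_method == "circular":
        null = np.empty(n_boot)
        for r in range(n_boot):
            off = int(rng.integers(1, t_len - 1))
            null[r] = binned_mi_profile(np.roll(c, off), vb, lags_ms).max()
    elif null_method == "resample":
        nz = np.flatnonzero(c > 0)
        if nz.size == 0:
            null = np.zeros(n_boot)
        else:
            null = _null_im_kernel(c[nz], t_len, vb, vb_hists, shifts,
                                   win_lo, win_hi, kc, kv, int(n_boot),
                                   int(rng.integers(0, 2**31 - 1)))
    else:
        raise ValueError(f"unknown null_method {null_method!r}")

    prof.threshold = float(np.quantile(null, 0.99))
    prof.p_value = float(np.mean(null >= prof.i_m))
    prof.significant = bool(prof.i_m > prof.threshold)
    prof.null_quantiles = {q: float(np.quantile(null, q))
                           for q in (0.5, 0.95, 0.99)}
    return prof


# ---- DTW-warp control ------------------------------------------------------

def warp_trial_series(counts: np.ndarray, velocity: np.ndarray,
                      path: np.ndarray):
    """Map one trial's binned series through a DTW warp path.

    The path holds (trial_index, reference_index) pairs on the common
    12.5 ms frame grid.  Reference indices hit by several trial bins
    average the velocity and sum the counts; the returned series live on
    the reference time base.
    """
    path = np.asarray(path, int)
    if path[:, 0].max() >= len(counts) or path[:, 0].min() < 0:
        raise ValueError("warp path exceeds the trial window")
    n_ref = path[:, 1].max() + 1
    c_out = np.zeros(n_ref)
    v_sum = np.zeros(n_ref)
    v_n = np.zeros(n_ref)
    np.add.at(c_out, path[:, 1], counts[path[:, 0]])
    np.add.at(v_sum, path[:, 1], velocity[path[:, 0]])
    np.add.at(v_n, path[:, 1], 1.0)
    return c_out, v_sum / np.maximum(v_n, 1.0)


def warp_controlled_mi(trial_counts: list, trial_velocities: list,
                       warps: list, lags_ms: np.ndarray = LAG_GRID_MS,
                       n_velocity_bins: int = N_VELOCITY_BINS) -> MIProfile:
    """Re-computed I(tau) after warping each trial onto the reference.

    Inputs are per-trial binned spike counts and velocity series (12.5 ms
    grid over the analysis window) plus the per-trial DTW warp paths; the
    warped series are concatenated across trials before the MI profile is
    evaluated, removing across-trial variability of execution timing.
    """
    if not (len(trial_counts) == len(trial_velocities) == len(warps)):
        raise ValueError("per-trial inputs must align")
    cs, vs = [], []
    for c, v, w in zip(trial_counts, trial_velocities, warps):
        path = w.path if hasattr(w, "path") else np.asarray(w, int)
        cw, vw = warp_trial_series(np.asarray(c, float), np.asarray(v, float), path)
        cs.append(cw)
        vs.append(vw)
    counts = np.concatenate(cs)
    vel = np.concatenate(vs)
    codes, degenerate = _discretize_velocity(vel, n_velocity_bins)
    lags_ms = np.asarray(lags_ms, float)
    mi = np.zeros(lags_ms.size) if degenerate else binned_mi_profile(
        np.round(counts).astype(int), codes, lags_ms)
    i_best = int(np.argmax(mi))
    return MIProfile(lags_ms=lags_ms, mi_bits=mi, i_m=float(mi[i_best]),
                     tau_opt_ms=float(lags_ms[i_best]), degenerate=degenerate)


# --------------------------------------------------------------------------
# cell typing

def classify_pn_in(features: np.ndarray, seed: int = 0) -> np.ndarray:
    """Putative pyramidal-vs-interneuron split by waveform/rate k-means.

    ``features`` is (units, 3): valley-to-peak width (ms), valley/peak
    amplitude ratio, mean rate (Hz).  k-means (k=2, 20 restarts) on
    z-scored features; the cluster with narrower waveforms is labelled
    interneuron.  Returns a boolean ``is_interneuron`` array.
    """
    x = np.atleast_2d(np.asarray(features, float))
    if x.shape[0] < 4:
        raise InsufficientDataError("need >= 4 units for PN/IN k-means")
    sd = x.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("all-identical features: no cluster structure")
    z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=2, n_init=20, random_state=seed).fit(z)
    width_means = [x[km.labels_ == k, 0].mean() for k in (0, 1)]
    in_cluster = int(np.argmin(width_means))
    return km.labels_ == in_cluster


@dataclass
class TypeLabels:
    """Functional types of pyramidal units from their I_M trajectories."""

    types: np.ndarray                  # per-unit 1/2/3
    cluster_ids: np.ndarray
    linkage: np.ndarray
    n_clusters: int
    ch_scores: dict
    tau_change_ms: dict                # per-type mean day-final minus day-1
    tau_change_p: dict                 # per-type paired t-test p
    flags: list = field(default_factory=list)


def cluster_im_types(im: np.ndarray, tau: np.ndarray, sig: np.ndarray,
                     k_range=range(2, 9)) -> TypeLabels:
    """Ward clustering of per-unit I_M vectors and rule-based typing.

    ``im``/``tau``/``sig`` are (units, days) matrices of I_M (bits),
    tau_opt (ms) and the per-day significance flag.  Agglomeration uses
    Euclidean distance between I_M vectors with Ward's minimum-variance
    criterion; the cluster count maximizes the Calinski-Harabasz score
    over ``k_range``.  Each cluster is mapped to a functional type by the
    majority rule over its members: type 1 when I_M is significant on
    both the first and final day (stable movement-coding), type 2 when
    significant only on the final day (task-recruited), type 3 otherwise.
    Per-type tau_opt change (final minus first day) is reported with a
    paired t-test.
    """
    im = np.atleast_2d(np.asarray(im, float))
    n_units, n_days = im.shape
    if n_days < 2:
        raise ValueError("need >= 2 days of I_M per unit")
    flags = []
    ks = [k for k in k_range if k < n_units]
    if len(ks) < len(list(k_range)):
        flags.append("k_range_clipped")
    if not ks:
        raise InsufficientDataError("fewer units than the smallest cluster count")
    link = linkage(im, method="ward", metric="euclidean")
    ch = {}
    for k in ks:
        labs = fcluster(link, k, criterion="maxclust")
        ch[k] = (calinski_harabasz_score(im, labs)
                 if np.unique(labs).size > 1 else -np.inf)
    k_best = max(ch, key=ch.get)
    clusters = fcluster(link, k_best, criterion="maxclust")

    sig = np.asarray(sig, bool)
    unit_rule = np.where(sig[:, 0] & sig[:, -1], 1,
                         np.where(~sig[:, 0] & sig[:, -1], 2, 3))
    types = np.empty(n_units, dtype=int)
    for cid in np.unique(clusters):
        members = clusters == cid
        vals, counts = np.unique(unit_rule[members], return_counts=True)
        types[members] = vals[np.argmax(counts)]

    tau = np.asarray(tau, float)
    tau_change, tau_p = {}, {}
    for t in (1, 2, 3):
        m = types == t
        if m.sum() >= 2:
            d = tau[m, -1] - tau[m, 0]
            tau_change[t] = float(np.mean(d))
            tau_p[t] = float(stats.ttest_rel(tau[m, -1], tau[m, 0]).pvalue)
        elif m.sum() == 1:
            tau_change[t] = float(tau[m, -1][0] - tau[m, 0][0])
            tau_p[t] = np.nan
    return TypeLabels(types=types, cluster_ids=clusters, linkage=link,
                      n_clusters=k_best, ch_scores=ch,
                      tau_change_ms=tau_change, tau_change_p=tau_p, flags=flags)


# --------------------------------------------------------------------------
# mean-matched Fano factor

def sliding_spike_counts(spikes: SpikeTrain, events: np.ndarray,
                         t_range: tuple = (-1.0, 1.0),
                         window_s: float = 0.05, step_s: float = 0.01):
    """(trials, bins) spike counts in a sliding window around events."""
    events = np.atleast_1d(np.asarray(events, float))
    starts = np.arange(t_range[0], t_range[1] - window_s + 1e-9, step_s)
    centers = starts + window_s / 2
    out = np.empty((events.size, starts.size), dtype=int)
    for i, ev in enumerate(events):
        t = spikes.times
        lo = np.searchsorted(t, ev + starts, side="left")
        hi = np.searchsorted(t, ev + starts + window_s, side="left")
        out[i] = hi - lo
    return out, centers


@dataclass
class FanoResult:
    """Raw and mean-matched Fano factor over sliding time bins."""

    times_s: np.ndarray
    fano_raw: np.ndarray
    fano_matched: np.ndarray
    epoch_means: dict
    n_points_per_bin: np.ndarray


_EPOCHS = {"pre_grasp": (-1.0, -0.5), "peri_grasp": (-0.25, 0.25),
           "post_grasp": (0.5, 1.0)}


def _ff_slope(means: np.ndarray, variances: np.ndarray) -> float:
    """Variance-vs-mean regression slope through the origin."""
    denom = np.sum(means**2)
    if denom <= 0:
        return np.nan
    return float(np.sum(means * variances) / denom)


def mean_matched_fano(counts, times_s: np.ndarray | None = None,
                      n_mean_bins: int = 20, n_repeats: int = 50,
                      seed: int = 0, epochs: dict = _EPOCHS) -> FanoResult:
    """Mean-matched Fano factor across a unit population.

    ``counts`` is a list of (trials, bins) arrays, one per unit, on a
    common sliding-window grid ``times_s``.  Per time bin each unit
    contributes one (mean, variance) point across trials; the raw FF is
    the regression slope of variance on mean through the origin.  Mean
    matching computes the greatest common distribution of means across
    bins on a fixed grid and randomly subsamples every bin's points to
    match it (``n_repeats`` seeded repeats, averaged), so FF changes
    cannot be driven by rate changes alone.
    """
    counts = [np.atleast_2d(np.asarray(c, float)) for c in counts]
    if any(c.shape[0] < 2 for c in counts):
        raise InsufficientDataError("need >= 2 trials per unit")
    n_bins = counts[0].shape[1]
    if times_s is None:
        times_s = np.arange(n_bins, dtype=float)
    means = np.stack([c.mean(axis=0) for c in counts])       # (units, bins)
    varis = np.stack([c.var(axis=0, ddof=1) for c in counts])
    if np.all(means == 0):
        return FanoResult(times_s=times_s, fano_raw=np.full(n_bins, np.nan),
                          fano_matched=np.full(n_bins, np.nan),
                          epoch_means={k: np.nan for k in epochs},
                          n_points_per_bin=np.zeros(n_bins, int))
    fano_raw = np.array([_ff_slope(means[:, b], varis[:, b])
                         for b in range(n_bins)])

    # greatest common mean-count distribution across bins; if the grid is
    # so fine that no cell survives the across-bin minimum, coarsen it
    lo, hi = means.min(), means.max() + 1e-9
    k = n_mean_bins
    while True:
        edges = np.linspace(lo, hi, k + 1)
        cell = np.clip(np.digitize(means, edges) - 1, 0, k - 1)
        hist = np.stack([np.bincount(cell[:, b], minlength=k)
                         for b in range(n_bins)])            # (bins, cells)
        common = hist.min(axis=0)
        if common.sum() > 0 or k == 1:
            break
        k = max(k // 2, 1)

    rng = np.random.default_rng(seed)
    fano_m = np.zeros(n_bins)
    n_pts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        reps = []
        for _ in range(n_repeats):
            keep = []
            for cidx in np.flatnonzero(common):
                members = np.flatnonzero(cell[:, b] == cidx)
                take = min(common[cidx], members.size)
                keep.extend(rng.choice(members, size=take, replace=False))
            if keep:
                keep = np.asarray(keep)
                reps.append(_ff_slope(means[keep, b], varis[keep, b]))
        fano_m[b] = np.nanmean(reps) if reps else np.nan
        n_pts[b] = int(common.sum())
    epoch_means = {}
    for name, (t0, t1) in epochs.items():
        m = (times_s >= t0) & (times_s <= t1)
        epoch_means[name] = float(np.nanmean(fano_m[m])) if m.any() else np.nan
    return FanoResult(times_s=times_s, fano_raw=fano_raw, fano_matched=fano_m,
                      epoch_means=epoch_means, n_points_per_bin=n_pts)
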