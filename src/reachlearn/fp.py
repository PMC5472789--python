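"""Evoked field potentials, learning-related LTP, and current source density.

Evoked FPs recorded on a laminar probe (20 channels, 100 um spacing,
1 kHz) are averaged over sweeps; the amplitude is the peak negativity
relative to the pre-stimulus baseline and the initial slope a least
squares fit over the 20-80% rising segment.  An input-output curve over
stimulus intensities selects the test intensity (the intensity evoking
50% of the maximal amplitude, configurable within 25-75%); potentiation
is tracked as percent of the pre-training baseline.  The 1D current
source density relates the laminar potential profile to the underlying
trans-membrane currents, C = -sigma * d2(phi)/dz2, estimated either by
the second spatial difference (with duplicated boundary channels) or by
the spline-inverse method (forward matrix under a cubic-spline source
assumption, inverted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import binomtest

__all__ = [
    "LaminarFP", "CSDProfile", "FPMeasure", "LTPSeries",
    "measure_fp", "build_io_curve", "ltp_timecourse", "estimate_csd",
    "day_boundary_sign_test",
]


@dataclass
class LaminarFP:
    """Laminar sweep array: (sweeps, channels, samples) in mV at 1 kHz."""

    sweeps: np.ndarray
    depths_um: np.ndarray
    fs_hz: float = 1000.0
    stim_onset_index: int = 0
    sigma_s_per_m: float = 0.3
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sweeps = np.asarray(self.sweeps, float)
        if self.sweeps.ndim == 2:
            self.sweeps = self.sweeps[None, :, :]
        self.depths_um = np.asarray(self.depths_um, float)
        d = np.diff(self.depths_um)
        if np.any(d <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.ptp(d) > 1e-6 * np.mean(d):
            raise ValueError("non-uniform channel spacing; resample first")
        if self.depths_um.size < 3:
            raise ValueError("CSD needs >= 3 channels")

    @property
    def n_channels(self) -> int:
        return self.depths_um.size

    @property
    def spacing_um(self) -> float:
        return float(self.depths_um[1] - self.depths_um[0])

    def mean_sweep(self) -> np.ndarray:
        return self.sweeps.mean(axis=0)


@dataclass
class CSDProfile:
    """Depth-resolved current source density (sink negative)."""

    depths_um: np.ndarray
    csd: np.ndarray                    # (depths,) or (depths, samples)
    method: str
    balance: float = np.nan            # sum(C * dz), ~0 for balanced profiles
    condition_number: float = np.nan


@dataclass
class FPMeasure:
    """Amplitude and initial slope of a sweep-averaged evoked FP."""

    amplitude_mv: float
    slope_mv_per_ms: float
    n_sweeps: int
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")


@dataclass
class LTPSeries:
    """Percent-of-baseline potentiation per session."""

    sessions: np.ndarray
    amplitude_pct: np.ndarray
    slope_pct: np.ndarray
    baseline_sessions: np.ndarray

    def __post_init__(self):
        if np.any(self.amplitude_pct <= 0) or np.any(
                self.slope_pct[np.isfinite(self.slope_pct)] <= 0):
            raise ValueError("percent-of-baseline values must be > 0")


def measure_fp(sweeps: np.ndarray, stim_onset: int, fs_hz: float = 1000.0,
               baseline_window: tuple | None = None,
               slope_span: tuple = (0.2, 0.8)) -> FPMeasure:
    """Amplitude and initial slope of the averaged evoked FP.

    ``sweeps`` is (n_sweeps, samples) from one channel; sweeps are
    averaged, the amplitude is the post-stimulus peak negativity minus
    the pre-stimulus baseline mean (negative value for a downward FP),
    and the slope a least squares fit over the ``slope_span`` fraction of
    the rise toward the peak.  Returns NaN amplitude (flagged) when no
    negative deflection follows the stimulus.
    """
    sweeps = np.atleast_2d(np.asarray(sweeps, float))
    avg = sweeps.mean(axis=0)
    flags = []
    if baseline_window is None:
        baseline_window = (0, stim_onset)
    b0, b1 = baseline_window
    base = float(avg[b0:b1].mean()) if b1 > b0 else 0.0
    post = avg[stim_onset:]
    if post.size == 0 or post.min() >= base:
        return FPMeasure(amplitude_mv=np.nan, slope_mv_per_ms=np.nan,
                         n_sweeps=sweeps.shape[0],
                         flags=["no_negative_deflection"])
    i_peak = int(np.argmin(post)) + stim_onset
    amplitude = float(avg[i_peak] - base)
    # rising (falling-voltage) segment between slope_span of the excursion
    seg = avg[stim_onset:i_peak + 1]
    exc = seg - base
    lo_f, hi_f = slope_span
    lvl_lo, lvl_hi = amplitude * lo_f, amplitude * hi_f
    in_span = np.flatnonzero((exc <= lvl_lo) & (exc >= lvl_hi))
    if in_span.size < 2:
        in_span = np.arange(len(seg))
        flags.append("slope_span_fallback")
    t_ms = (np.arange(len(seg)) / fs_hz) * 1000.0
    slope = float(np.polyfit(t_ms[in_span], seg[in_span], 1)[0])
    return FPMeasure(amplitude_mv=amplitude, slope_mv_per_ms=slope,
                     n_sweeps=sweeps.shape[0], flags=flags)


#: intensity grid used in the emulated experiment (uA)
IO_INTENSITIES_UA = (40, 60, 80, 100, 200, 400, 600, 800, 1000)


def build_io_curve(sweep_sets: list, intensities, stim_onset: int,
                   fs_hz: float = 1000.0, target_fraction: float = 0.5):
    """Input-output curve and test-intensity selection.

    ``sweep_sets[i]`` holds the sweeps recorded at ``intensities[i]``.
    The test intensity is the one evoking ``target_fraction`` (default
    50%, admissible 25-75%) of the maximal amplitude, found by linear
    interpolation on the measured curve.  A non-monotone curve (beyond
    5% of the range) is flagged and replaced by its isotonic fit.
    """
    if not 0.25 <= target_fraction <= 0.75:
        raise ValueError("target fraction must lie within 25-75%")
    intensities = np.asarray(intensities, float)
    if intensities.size < 3:
        raise ValueError("need >= 3 intensities")
    amps = np.array([measure_fp(s, stim_onset, fs_hz).amplitude_mv
                     for s in sweep_sets])
    if np.all(np.isnan(amps)):
        raise ValueError("no measurable FP at any intensity (flat curve)")
    mag = -amps            # positive magnitudes, increasing with intensity
    warning = None
    if np.any(np.diff(mag) < -0.05 * np.ptp(mag)):
        warning = "non-monotone input-output curve; using isotonic fit"
        from sklearn.isotonic import IsotonicRegression
        mag = IsotonicRegression(increasing=True).fit_transform(intensities, mag)
    if np.ptp(mag) <= 0:
        raise ValueError("flat input-output curve")
    target = target_fraction * mag.max()
    test_intensity = float(np.interp(target, mag, intensities))
    curve = {"intensities_ua": intensities, "amplitude_mv": amps,
             "magnitude_mv": mag, "warning": warning}
    return curve, test_intensity


def ltp_timecourse(measures: list, baseline_sessions: np.ndarray) -> LTPSeries:
    """Percent-of-baseline time course of FP slope and amplitude.

    ``measures`` is a per-session list of FPMeasure; ``baseline_sessions``
    indexes the pre-training sessions whose mean defines 100%.
    """
    baseline_sessions = np.asarray(baseline_sessions, int)
    if baseline_sessions.size < 1:
        raise ValueError("need >= 1 baseline session")
    amp = np.array([m.amplitude_mv for m in measures])
    slp = np.array([m.slope_mv_per_ms for m in measures])
    base_amp = np.nanmean(np.abs(amp[baseline_sessions]))
    base_slp = np.nanmean(np.abs(slp[baseline_sessions]))
    if not np.isfinite(base_amp) or base_amp == 0:
        raise ValueError("zero or undefined baseline amplitude")
    amp_pct = 100.0 * np.abs(amp) / base_amp
    slp_pct = 100.0 * np.abs(slp) / base_slp if base_slp > 0 else \
        np.full_like(amp_pct, np.nan)
    return LTPSeries(sessions=np.arange(len(measures)), amplitude_pct=amp_pct,
                     slope_pct=slp_pct, baseline_sessions=baseline_sessions)


def day_boundary_sign_test(values: np.ndarray, sessions_per_day: int):
    """Sign test on overnight steps of a per-session potentiation series.

    Returns ``(n_negative, n_steps, p_value)`` for the null that
    overnight steps (first session of day k+1 minus last of day k) are
    symmetric around zero.  Overnight de-potentiation (lesion scenario)
    shows up as predominantly negative steps.
    """
    v = np.asarray(values, float)
    n_days = v.size // sessions_per_day
    steps = [v[(d + 1) * sessions_per_day] - v[(d + 1) * sessions_per_day - 1]
             for d in range(n_days - 1)
             if (d + 1) * sessions_per_day < v.size]
    steps = np.asarray(steps)
    steps = steps[steps != 0]
    if steps.size == 0:
        return 0, 0, 1.0
    n_neg = int((steps < 0).sum())
    p = binomtest(n_neg, steps.size, 0.5).pvalue
    return n_neg, steps.size, float(p)


# --------------------------------------------------------------------------
# current source density

def _spline_forward_matrix(depths_m: np.ndarray, sigma: float,
                           disc_radius_m: float, n_fine: int = 20):
    """Forward matrix mapping node CSD values to channel potentials.

    The CSD is assumed continuous in depth (natural cubic spline through
    the channel-node values) and homogeneous within a disc of radius
    ``disc_radius_m`` in the lateral plane.  The potential of a disc
    source layer at distance is the standard electrostatic expression
    phi(z) = C/(2 sigma) * (sqrt((z-z')^2 + R^2) - |z-z'|) integrated
    over depth.
    """
    n = depths_m.size
    h = depths_m[1] - depths_m[0]
    z_lo, z_hi = depths_m[0] - h / 2, depths_m[-1] + h / 2
    zf = np.linspace(z_lo, z_hi, n * n_fine)
    dz = zf[1] - zf[0]
    # spline basis: column k = spline through unit vector e_k
    basis = np.empty((zf.size, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = 1.0
        basis[:, k] = CubicSpline(depths_m, e, bc_type="natural")(zf)
    kern = (np.sqrt((depths_m[:, None] - zf[None, :]) ** 2 + disc_radius_m**2)
            - np.abs(depths_m[:, None] - zf[None, :])) / (2.0 * sigma)
    return (kern * dz) @ basis          # (channels, nodes)


def estimate_csd(fp: LaminarFP, method: str = "second_difference",
                 disc_diameter_um: float = 500.0,
                 cond_limit: float = 1e8) -> CSDProfile:
    """Invert laminar FPs to a current source density profile.

    ``second_difference``: C(z) = -sigma [phi(z+h) - 2 phi(z) + phi(z-h)] / h^2
    with boundary channels handled by duplication, returning C on the
    full channel grid in units of A/m^3 scale (mV inputs are converted
    to V).  ``spline_inverse``: builds the forward matrix F under a
    cubic-spline source assumption and returns C = F^-1 phi; an
    ill-conditioned F is regularized by a pseudo-inverse and the
    condition number recorded.
    """
    phi = fp.mean_sweep() * 1e-3        # mV -> V, (channels, samples)
    h_m = fp.spacing_um * 1e-6
    sigma = fp.sigma_s_per_m
    if method in ("second_difference", "second-difference"):
        padded = np.vstack([phi[:1], phi, phi[-1:]])   # Vaknin duplication
        csd = -sigma * (padded[2:] - 2 * padded[1:-1] + padded[:-2]) / h_m**2
        cond = np.nan
        tag = "second-difference"
    elif method in ("spline_inverse", "spline-inverse"):
        f = _spline_forward_matrix(fp.depths_um * 1e-6, sigma,
                                   disc_diameter_um * 1e-6 / 2.0)
        cond = float(np.linalg.cond(f))
        if cond > cond_limit:
            csd = np.linalg.pinv(f, rcond=1e-10) @ phi
        else:
            csd = np.linalg.solve(f, phi)
        tag = "spline-inverse"
    else:
        raise ValueError(f"unknown CSD method {method!r}")
    balance = float(np.sum(csd.sum(axis=0)) * h_m) if csd.ndim > 1 else \
        float(csd.sum() * h_m)
    return CSDProfile(depths_um=fp.depths_um, csd=csd, method=tag,
                      balance=balance, condition_number=cond)
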