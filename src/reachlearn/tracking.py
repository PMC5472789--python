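"""Cross-day tracking of chronically recorded single units.

Whether day-k and day-1 recordings of a cluster come from the same neuron
is decided from four similarity scores — Fisher-transformed maximum
time-shifted waveform correlation (Max r), normalized peak-to-peak
amplitude difference, and symmetrized Kullback-Leibler divergences of
log-binned ISI histograms and autocorrelograms — fed to a two-class
Gaussian model with a quadratic (QDA) decision boundary.  The boundary is
calibrated to a 5% error rate on known distinct-neuron ("true negative")
pairs, and a conservative rule additionally requires the scores to fall
outside the 3 s.d. Mahalanobis contour of the distinct-pair cloud.  A
unit counts as stably tracked only if every day passes both rules.

Score conventions: divergences are log1p-transformed before the Gaussian
fit (divergence scores are heavily right-skewed); the feature pair used
by default is chosen among the six 2-subsets by AIC/BIC of the pooled
two-class Gaussian likelihood.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import InsufficientDataError, SpikeTrain
from .quality import WaveformSet

__all__ = [
    "SimilarityScores", "TrackingModel", "TrackingDecision",
    "compute_similarity_scores", "fit_tracking_classifier",
    "classify_unit_track", "estimate_error_rates",
    "symmetrized_kl", "isi_histogram", "autocorrelogram",
]

SCORE_NAMES = ("max_r_z", "d_pamp", "isih_div", "acorr_div")
#: default transform per score before Gaussian fitting
_DIVERGENCE_SCORES = {"isih_div", "acorr_div"}

ISIH_RANGE_MS = (0.5, 1e5)
ISIH_BINS = 100
ACORR_MAX_LAG_MS = 100.0
ACORR_BINS = 100
MAX_SHIFT_SAMPLES = 5
MIN_SPIKES = 50
_EPS = 1e-10   # pseudocount per histogram bin


@dataclass
class SimilarityScores:
    """Four cross-day similarity features of one (reference, current) pair."""

    max_r_z: float
    d_pamp: float
    isih_div: float
    acorr_div: float
    day: int | None = None
    flags: list = field(default_factory=list)

    def as_array(self, names=SCORE_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    def __post_init__(self):
        if self.d_pamp < 0 or self.isih_div < 0 or self.acorr_div < 0:
            raise ValueError("divergence/amplitude scores must be >= 0")


def symmetrized_kl(p: np.ndarray, q: np.ndarray, eps: float = _EPS) -> float:
    """Jeffreys-averaged KL divergence in bits between two histograms.

    Histograms are pseudocount-regularized and renormalized, so the
    result is finite, symmetric in its arguments and zero iff p == q.
    """
    p = np.asarray(p, float) + eps
    q = np.asarray(q, float) + eps
    p = p / p.sum()
    q = q / q.sum()
    kl_pq = np.sum(p * np.log2(p / q))
    kl_qp = np.sum(q * np.log2(q / p))
    return float(0.5 * (kl_pq + kl_qp))


def isi_histogram(train: SpikeTrain, bins: int = ISIH_BINS,
                  range_ms: tuple = ISIH_RANGE_MS) -> np.ndarray:
    """ISI histogram on a log-spaced grid (0.5 to 1e5 ms, 100 bins)."""
    edges = np.logspace(np.log10(range_ms[0]), np.log10(range_ms[1]), bins + 1)
    isi_ms = train.isi() * 1000.0
    return np.histogram(isi_ms, bins=edges)[0].astype(float)


def autocorrelogram(train: SpikeTrain, bins: int = ACORR_BINS,
                    max_lag_ms: float = ACORR_MAX_LAG_MS) -> np.ndarray:
    """Log-binned spike autocorrelogram over +/- max_lag (100 bins).

    |lag| is binned on a log grid from 0.5 ms to the maximum lag with
    bins/2 bins, mirrored to negative lags.  The zero-lag (self) pairs are
    excluded.
    """
    half = bins // 2
    edges = np.logspace(np.log10(0.5), np.log10(max_lag_ms), half + 1)
    t = train.times
    counts = np.zeros(half)
    if t.size >= 2:
        max_s = max_lag_ms / 1000.0
        # forward lags only; histogram is symmetric by construction
        j0 = 0
        lags = []
        for i in range(t.size - 1):
            j = i + 1
            while j < t.size and t[j] - t[i] <= max_s:
                lags.append((t[j] - t[i]) * 1000.0)
                j += 1
        if lags:
            counts = np.histogram(lags, bins=edges)[0].astype(float)
    return np.concatenate([counts[::-1], counts])


def _max_shifted_correlation(a: np.ndarray, b: np.ndarray,
                             max_shift: int = MAX_SHIFT_SAMPLES):
    """Max Pearson r between two mean waveforms over integer shifts."""
    best_r, best_s = -np.inf, 0
    n = a.size
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            x, y = a[s:], b[:n - s]
        else:
            x, y = a[:n + s], b[-s:]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best_r:
            best_r, best_s = r, s
    return best_r, best_s


def compute_similarity_scores(ref, cur, min_spikes: int = MIN_SPIKES) -> SimilarityScores:
    """Similarity scores between a reference and a current recording.

    ``ref`` and ``cur`` are ``(WaveformSet, SpikeTrain)`` pairs; the
    reference is normally day 1.  Requires at least ``min_spikes`` spikes
    in both trains.
    """
    (wf_ref, st_ref), (wf_cur, st_cur) = ref, cur
    if st_ref.n_spikes < min_spikes or st_cur.n_spikes < min_spikes:
        raise InsufficientDataError(
            f"need >= {min_spikes} spikes per unit "
            f"(got {st_ref.n_spikes}, {st_cur.n_spikes})")
    flags = []
    mw_ref = wf_ref.mean_waveform()
    mw_cur = wf_cur.mean_waveform()
    r, _ = _max_shifted_correlation(mw_ref, mw_cur)
    r_clip = 1.0 - 1e-12
    if r >= r_clip:
        r = r_clip
        flags.append("r_clipped")
    if r <= -r_clip:
        r = -r_clip
    z = float(np.arctanh(r))
    ptp_ref = float(np.ptp(mw_ref))
    d_pamp = abs(float(np.ptp(mw_cur)) - ptp_ref) / ptp_ref if ptp_ref > 0 else np.nan
    isih = symmetrized_kl(isi_histogram(st_ref), isi_histogram(st_cur))
    acorr = symmetrized_kl(autocorrelogram(st_ref), autocorrelogram(st_cur))
    return SimilarityScores(max_r_z=z, d_pamp=d_pamp, isih_div=isih,
                            acorr_div=acorr, day=st_cur.day, flags=flags)


# --------------------------------------------------------------------------
# classifier

def _transform(values: np.ndarray, names: tuple) -> np.ndarray:
    """Per-score transform before Gaussian fitting (log1p for divergences)."""
    out = np.array(values, dtype=float, copy=True)
    for j, nm in enumerate(names):
        if nm in _DIVERGENCE_SCORES:
            out[..., j] = np.log1p(out[..., j])
    return out


def _fit_gauss(x: np.ndarray, flags: list):
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    if np.linalg.det(cov) <= 0:
        cov = cov + 1e-8 * (np.trace(cov) / cov.shape[0] + 1e-12) * np.eye(cov.shape[0])
        flags.append("class_covariance_regularized")
    return mean, cov


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    return stats.multivariate_normal(mean, cov, allow_singular=True).logpdf(x)


@dataclass
class TrackingModel:
    """Calibrated two-class Gaussian model over a pair of similarity scores.

    Scores are transformed (log1p for divergences) and standardized by
    the pooled training mean/s.d. before the Gaussian fit, so that model
    selection across feature pairs compares class structure rather than
    raw score scale.
    """

    feature_pair: tuple
    pos_mean: np.ndarray
    pos_cov: np.ndarray
    neg_mean: np.ndarray
    neg_cov: np.ndarray
    offset: float                      # calibrated decision offset
    scale_mean: np.ndarray = None
    scale_sd: np.ndarray = None
    sd_threshold: float = 3.0          # conservative Mahalanobis contour
    target_error: float = 0.05
    selection: dict = field(default_factory=dict)   # per-pair AIC/BIC records
    flags: list = field(default_factory=list)

    def _features(self, scores) -> np.ndarray:
        arr = np.atleast_2d(np.array(
            [s.as_array(self.feature_pair) if isinstance(s, SimilarityScores) else s
             for s in np.atleast_1d(scores)], dtype=float))
        x = _transform(arr, self.feature_pair)
        if self.scale_mean is not None:
            x = (x - self.scale_mean) / self.scale_sd
        return x

    def discriminant(self, scores) -> np.ndarray:
        """Calibrated quadratic log-likelihood ratio (>0 -> same neuron)."""
        x = self._features(scores)
        return np.atleast_1d(
            _log_gauss(x, self.pos_mean, self.pos_cov)
            - _log_gauss(x, self.neg_mean, self.neg_cov) + self.offset)

    def mahalanobis_to_negative(self, scores) -> np.ndarray:
        x = self._features(scores)
        d = x - self.neg_mean
        sol = np.linalg.solve(self.neg_cov, d.T)
        return np.sqrt(np.einsum("ij,ji->i", d, sol))

    def predict_same(self, scores) -> np.ndarray:
        """Same-neuron call: QDA positive AND outside 3 s.d. of negatives."""
        return (self.discriminant(scores) > 0) \
            & (self.mahalanobis_to_negative(scores) > self.sd_threshold)


@dataclass
class TrackingDecision:
    """Per-day same/distinct calls for one tracked unit."""

    days: np.ndarray
    same_per_day: np.ndarray
    discriminant: np.ndarray
    mahalanobis: np.ndarray
    stable: bool
    failure_day: int | None
    cumulative_fp: np.ndarray
    cumulative_fn: np.ndarray


def _default_pairs():
    return list(itertools.combinations(SCORE_NAMES, 2))


def fit_tracking_classifier(pos: list, neg: list, feature_pairs=None,
                            target_error: float = 0.05,
                            sd_threshold: float = 3.0) -> TrackingModel:
    """Fit and calibrate the two-class Gaussian tracking model.

    ``pos``/``neg`` are SimilarityScores (or 4-vectors) from known
    same-neuron and distinct-neuron pairs.  For each candidate feature
    pair a class-conditional bivariate Gaussian model is fitted; the pair
    minimizing BIC (AIC as tie-breaker, ties broken toward pairs
    containing ``max_r_z``) of the pooled two-component mixture is kept.
    The quadratic boundary is then shifted so the training-negative error
    is as close as possible to ``target_error``.
    """
    if len(pos) < 30 or len(neg) < 30:
        raise InsufficientDataError("need >= 30 observations per class")
    pos_full = np.array([s.as_array() if isinstance(s, SimilarityScores) else s
                         for s in pos], dtype=float)
    neg_full = np.array([s.as_array() if isinstance(s, SimilarityScores) else s
                         for s in neg], dtype=float)
    pairs = feature_pairs or _default_pairs()
    idx = {n: i for i, n in enumerate(SCORE_NAMES)}

    selection, candidates = {}, {}
    for pair in pairs:
        cols = [idx[n] for n in pair]
        xp = _transform(pos_full[:, cols], pair)
        xn = _transform(neg_full[:, cols], pair)
        pooled = np.vstack([xp, xn])
        mu = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        xp = (xp - mu) / sd
        xn = (xn - mu) / sd
        flags = []
        pm, pc = _fit_gauss(xp, flags)
        nm, nc = _fit_gauss(xn, flags)
        w = len(xp) / (len(xp) + len(xn))
        allx = np.vstack([xp, xn])
        ll = np.logaddexp(np.log(w) + _log_gauss(allx, pm, pc),
                          np.log(1 - w) + _log_gauss(allx, nm, nc)).sum()
        k = 11  # 2 means (2x2) + 2 covariances (2x3) + mixing weight
        n_tot = len(allx)
        aic = 2 * k - 2 * ll
        bic = k * np.log(n_tot) - 2 * ll
        selection[pair] = {"aic": aic, "bic": bic, "loglik": ll}
        candidates[pair] = (pm, pc, nm, nc, mu, sd, flags)

    def _rank(pair):
        s = selection[pair]
        return (round(s["bic"], 9), round(s["aic"], 9), 0 if "max_r_z" in pair else 1)

    # walk the information-criterion ranking; keep the first pair whose
    # calibrated boundary beats chance on the training data (degenerate
    # near-constant score pairs can win on likelihood without separating)
    for best in sorted(selection, key=_rank):
        pm, pc, nm, nc, mu, sd, flags = candidates[best]
        model = TrackingModel(feature_pair=best, pos_mean=pm, pos_cov=pc,
                              neg_mean=nm, neg_cov=nc, offset=0.0,
                              scale_mean=mu, scale_sd=sd,
                              sd_threshold=sd_threshold,
                              target_error=target_error,
                              selection=selection, flags=flags)
        # calibrate: choose the offset putting target_error of training
        # negatives on the positive side of the boundary
        raw = model.discriminant(neg)
        model.offset = -float(np.quantile(raw, 1.0 - target_error))
        achieved = float(np.mean(model.discriminant(neg) > 0))
        model.selection["calibration_achieved"] = achieved
        if abs(achieved - target_error) > 0.005 and len(neg) >= 200:
            model.flags.append("calibration_outside_tolerance")
        acc = 0.5 * (np.mean(model.discriminant(pos) > 0)
                     + np.mean(model.discriminant(neg) <= 0))
        if acc > 0.55:
            return model
    raise InsufficientDataError(
        "no feature pair separates the classes better than chance")


def classify_unit_track(model: TrackingModel, scores_by_day: list) -> TrackingDecision:
    """Combine per-day calls into a stable-tracking decision.

    The unit is stably tracked iff every day passes both the calibrated
    QDA call and the 3 s.d. rule.  Cumulative false-positive /
    false-negative estimates assume independence across days.
    """
    days = np.array([s.day if s.day is not None else i
                     for i, s in enumerate(scores_by_day)])
    if any(s is None for s in scores_by_day):
        raise InsufficientDataError("missing day in tracked score sequence")
    disc = model.discriminant(scores_by_day)
    maha = model.mahalanobis_to_negative(scores_by_day)
    same = (disc > 0) & (maha > model.sd_threshold)
    stable = bool(same.all())
    failure_day = int(days[np.argmin(same)]) if not stable else None
    fp_day = model.selection.get("calibration_achieved", model.target_error)
    d = np.arange(1, len(days) + 1)
    cum_fp = 1.0 - (1.0 - fp_day) ** d
    fn_day = model.selection.get("fn_rate", np.nan)
    cum_fn = 1.0 - (1.0 - fn_day) ** d if np.isfinite(fn_day) else np.full(len(d), np.nan)
    return TrackingDecision(days=days, same_per_day=same, discriminant=disc,
                            mahalanobis=maha, stable=stable,
                            failure_day=failure_day,
                            cumulative_fp=cum_fp, cumulative_fn=cum_fn)


def estimate_error_rates(model: TrackingModel, labelled: list):
    """Empirical FP/FN rates of the stable-tracking call on labelled pairs.

    ``labelled`` is a list of ``(scores, is_same)``.  Returns
    ``(fp_rate, fn_rate, fp_ci, fn_ci)`` with Wilson 95% binomial CIs;
    a missing class yields NaN for its rate.
    """
    if not labelled:
        raise InsufficientDataError("no labelled pairs")
    scores = [s for s, _ in labelled]
    truth = np.array([bool(t) for _, t in labelled])
    pred = model.predict_same(scores)

    def _rate_ci(err, n):
        if n == 0:
            return np.nan, (np.nan, np.nan)
        p = err / n
        lo, hi = stats.binomtest(int(err), int(n)).proportion_ci(0.95, method="wilson")
        return p, (lo, hi)

    n_neg = int((~truth).sum())
    n_pos = int(truth.sum())
    fp, fp_ci = _rate_ci(int(pred[~truth].sum()), n_neg)
    fn, fn_ci = _rate_ci(int((~pred[truth]).sum()), n_pos)
    model.selection["fn_rate"] = fn
    return fp, fn, fp_ci, fn_ci
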