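"""Support-vector-regression decoding of forelimb movement.

Instantaneous velocity (or displacement) at time t is predicted from the
preceding window of population spike counts on the 12.5 ms grid.  Each
neuron's optimal preceding window is found by single-neuron decoding
(tau_SVR, expected to be >= tau_opt of the MI profile when the neuron
leads movement); population decoding stacks lagged counts of all neurons
over the chosen window, normalizes each neuron's rate to [0, 1], and
fits a nu-formulation SVR with a radial-basis kernel, selecting cost and
kernel width by cross-validated grid search over (a subset of) the log2
ranges -5..10 and -10..5.  Accuracy is reported as the squared Pearson
correlation r^2 and the mean squared deviation between predicted and
actual behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.svm import NuSVR

from .core import InsufficientDataError
from .encoding import BIN_S

__all__ = [
    "DecoderModel", "DecodingResult",
    "select_decoding_window", "fit_population_decoder",
    "evaluate_decoder", "cross_day_transfer", "lagged_design",
]

#: admissible log2 ranges for the RBF grid search
LOG2C_RANGE = (-5, 10)
LOG2G_RANGE = (-10, 5)
#: default searched grid: a coarse subset of the admissible ranges
DEFAULT_LOG2C = (-2.0, 2.0, 6.0)
DEFAULT_LOG2G = (-6.0, -2.0, 2.0)
_MAX_ITER = 500_000
WINDOW_GRID_MS = np.arange(12.5, 500.0 + 1e-9, 12.5)


def lagged_design(rates: np.ndarray, window_bins: int) -> np.ndarray:
    """Design matrix of preceding activity.

    ``rates`` is (neurons, time bins); row t of the output stacks each
    neuron's counts over bins [t - window + 1, t], zero-padded at the
    start, giving dimensionality ``n_neurons * window_bins``.
    """
    r = np.atleast_2d(np.asarray(rates, float))
    n, t = r.shape
    cols = []
    for lag in range(window_bins):
        shifted = np.zeros_like(r)
        if lag:
            shifted[:, lag:] = r[:, :-lag]
        else:
            shifted = r
        cols.append(shifted)
    return np.concatenate(cols, axis=0).T   # (t, n*window)


def _norm01(x: np.ndarray, lo=None, hi=None):
    lo = x.min(axis=0) if lo is None else lo
    hi = x.max(axis=0) if hi is None else hi
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return (x - lo) / span, lo, hi


def _r2_msd(pred: np.ndarray, target: np.ndarray):
    if np.std(pred) == 0 or np.std(target) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(pred, target)[0, 1] ** 2)
    msd = float(np.mean((pred - target) ** 2))
    return r2, msd


@dataclass
class DecoderModel:
    """Fitted population SVR decoder (one regressor per target column)."""

    window_ms: float
    neuron_ids: list
    nu: float
    log2c: float
    log2g: float
    estimators: list
    input_lo: np.ndarray
    input_hi: np.ndarray
    train_day: int | None = None
    cv_mse: float = np.nan
    searched_grid: tuple = (DEFAULT_LOG2C, DEFAULT_LOG2G)

    @property
    def window_bins(self) -> int:
        return int(round(self.window_ms / (BIN_S * 1000.0)))

    def predict(self, rates: np.ndarray) -> np.ndarray:
        x = lagged_design(rates, self.window_bins)
        x, _, _ = _norm01(x, self.input_lo, self.input_hi)
        preds = np.column_stack([est.predict(x) for est in self.estimators])
        return preds[:, 0] if preds.shape[1] == 1 else preds


@dataclass
class DecodingResult:
    """Held-out decoding accuracy of one (train day, test day) evaluation."""

    predicted: np.ndarray
    r2: float
    msd: float
    train_day: int | None = None
    test_day: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0 + 1e-9):
            raise ValueError("r2 outside [0, 1]")
        if self.msd < 0:
            raise ValueError("msd must be >= 0")


def _cv_r2(x: np.ndarray, y: np.ndarray, nu: float, c: float, g: float,
           n_splits: int = 5):
    """Cross-validated (r2, mse) of a NuSVR on a normalized design."""
    kf = KFold(n_splits=n_splits, shuffle=False)
    preds = np.empty_like(y)
    for tr, te in kf.split(x):
        est = NuSVR(nu=nu, C=c, gamma=g, max_iter=_MAX_ITER)
        est.fit(x[tr], y[tr])
        preds[te] = est.predict(x[te])
    return _r2_msd(preds, y)


def select_decoding_window(rates: np.ndarray, velocity: np.ndarray,
                           nu: float = 0.5, log2c: float = 0.0,
                           log2g: float = -2.0,
                           window_grid_ms: np.ndarray = WINDOW_GRID_MS,
                           n_shuffles: int = 20, seed: int = 0):
    """Optimal preceding window (tau_SVR, ms) for one neuron.

    Grid-searches window sizes (multiples of 12.5 ms up to 500 ms)
    maximizing cross-validated single-neuron prediction r^2.  A neuron
    whose best r^2 does not exceed the 95th percentile of a
    shuffled-target chance band is non-informative and returns NaN.
    """
    r = np.atleast_2d(np.asarray(rates, float))
    y = np.asarray(velocity, float)
    scores = []
    for w_ms in window_grid_ms:
        w = int(round(w_ms / (BIN_S * 1000.0)))
        x = lagged_design(r, w)
        x, _, _ = _norm01(x)
        scores.append(_cv_r2(x, y, nu, 2.0**log2c, 2.0**log2g)[0])
    scores = np.asarray(scores)
    best = int(np.argmax(scores))
    # chance band from circularly shifted targets at the best window:
    # rotation preserves the target's autocorrelation, so the band also
    # captures the spurious r^2 a smooth target produces on its own
    rng = np.random.default_rng(seed)
    w = int(round(window_grid_ms[best] / (BIN_S * 1000.0)))
    x = lagged_design(r, w)
    x, _, _ = _norm01(x)
    n = y.size
    chance = []
    for _ in range(n_shuffles):
        off = int(rng.integers(n // 4, 3 * n // 4))
        chance.append(_cv_r2(x, np.roll(y, off), nu, 2.0**log2c,
                             2.0**log2g)[0])
    # Sidak-adjust the band quantile for the best-of-grid selection
    q = 0.95 ** (1.0 / len(window_grid_ms))
    if scores[best] <= np.quantile(chance, q):
        return np.nan, scores
    return float(window_grid_ms[best]), scores


def fit_population_decoder(rates: np.ndarray, target: np.ndarray,
                           window_ms: float, nu: float = 0.5,
                           log2c_grid=DEFAULT_LOG2C, log2g_grid=DEFAULT_LOG2G,
                           n_splits: int = 5, neuron_ids=None,
                           train_day: int | None = None) -> DecoderModel:
    """Population nu-SVR fit with 5-fold CV grid search over (c, g).

    ``rates`` is (neurons, bins); ``target`` the aligned velocity series
    (or an (bins, 2) displacement array handled as two independent
    regressions).  Inputs are linearly normalized to [0, 1] per design
    column.  Constant targets are refused.
    """
    r = np.atleast_2d(np.asarray(rates, float))
    y = np.asarray(target, float)
    y2 = y[:, None] if y.ndim == 1 else y
    if r.shape[1] != y2.shape[0]:
        raise ValueError("rates/target span mismatch")
    if np.any(np.ptp(y2, axis=0) == 0):
        raise ValueError("degenerate (constant) target; fit refused")
    for g_ in np.atleast_1d(log2c_grid):
        if not (LOG2C_RANGE[0] <= g_ <= LOG2C_RANGE[1]):
            raise ValueError("log2 c grid outside the admissible range")
    for g_ in np.atleast_1d(log2g_grid):
        if not (LOG2G_RANGE[0] <= g_ <= LOG2G_RANGE[1]):
            raise ValueError("log2 g grid outside the admissible range")
    w = int(round(window_ms / (BIN_S * 1000.0)))
    if w < 1:
        raise ValueError("window must be >= 12.5 ms")
    x = lagged_design(r, w)
    x, lo, hi = _norm01(x)

    best = (np.inf, None, None)
    for lc in log2c_grid:
        for lg in log2g_grid:
            mse = 0.0
            for col in range(y2.shape[1]):
                mse += _cv_r2(x, y2[:, col], nu, 2.0**lc, 2.0**lg,
                              n_splits)[1]
            if mse < best[0]:
                best = (mse, lc, lg)
    _, lc, lg = best
    ests = []
    for col in range(y2.shape[1]):
        est = NuSVR(nu=nu, C=2.0**lc, gamma=2.0**lg, max_iter=_MAX_ITER)
        est.fit(x, y2[:, col])
        ests.append(est)
    return DecoderModel(window_ms=float(window_ms),
                        neuron_ids=list(neuron_ids) if neuron_ids is not None
                        else list(range(r.shape[0])),
                        nu=nu, log2c=float(lc), log2g=float(lg),
                        estimators=ests, input_lo=lo, input_hi=hi,
                        train_day=train_day, cv_mse=float(best[0]),
                        searched_grid=(tuple(log2c_grid), tuple(log2g_grid)))


def evaluate_decoder(model: DecoderModel, rates: np.ndarray,
                     target: np.ndarray,
                     test_day: int | None = None) -> DecodingResult:
    """r^2 and mean squared deviation of a fitted decoder on held-out data."""
    r = np.atleast_2d(np.asarray(rates, float))
    y = np.asarray(target, float)
    y1 = y if y.ndim == 1 else y[:, 0]
    if r.shape[1] != (y.shape[0] if y.ndim == 1 else y.shape[0]):
        raise ValueError("rates/target span mismatch")
    if r.shape[0] != len(model.neuron_ids):
        raise ValueError("feature dimension does not match the model")
    pred = model.predict(r)
    p1 = pred if pred.ndim == 1 else pred[:, 0]
    r2, msd = _r2_msd(p1, y1)
    if y.ndim == 2 and pred.ndim == 2:
        r2s, msds = zip(*[_r2_msd(pred[:, k], y[:, k])
                          for k in range(y.shape[1])])
        r2, msd = float(np.mean(r2s)), float(np.mean(msds))
    return DecodingResult(predicted=pred, r2=r2, msd=msd,
                          train_day=model.train_day, test_day=test_day)


def cross_day_transfer(models: dict, data: dict) -> dict:
    """Evaluate each day's decoder on the previous day (and same day held out).

    ``models`` maps day -> DecoderModel, ``data`` maps day ->
    ``(rates, target)``.  The same-day entry holds out the final 20% time
    block (fit happens upstream on the first 80%); previous-day transfer
    uses that day's full span.  Returns
    ``{(train_day, test_day): DecodingResult}``; a single day yields an
    empty table.
    """
    days = sorted(models)
    for d in days:
        if set(models[d].neuron_ids) != set(models[days[0]].neuron_ids):
            missing = set(models[days[0]].neuron_ids) ^ set(models[d].neuron_ids)
            raise ValueError(f"neuron-set mismatch across days: {sorted(missing)}")
    out = {}
    if len(days) < 2:
        return out
    for d in days:
        rates, target = data[d]
        n = np.atleast_2d(rates).shape[1]
        split = int(0.8 * n)
        out[(d, d)] = evaluate_decoder(models[d],
                                       np.atleast_2d(rates)[:, split:],
                                       np.asarray(target)[split:], test_day=d)
        prev = d - 1
        if prev in data:
            r_prev, t_prev = data[prev]
            out[(d, prev)] = evaluate_decoder(models[d], r_prev, t_prev,
                                              test_day=prev)
    return out


def shuffle_chance_band(model: DecoderModel, rates: np.ndarray,
                        target: np.ndarray, n_shuffles: int = 100,
                        seed: int = 0, q: float = 0.95) -> float:
    """q-quantile of r^2 under circular target shifts (chance band).

    Rotation destroys the prediction/target pairing while preserving the
    target's autocorrelation, so the band covers the spurious r^2 a
    smooth target yields against any smooth prediction.
    """
    rng = np.random.default_rng(seed)
    pred = model.predict(np.atleast_2d(rates))
    p1 = pred if pred.ndim == 1 else pred[:, 0]
    y = np.asarray(target, float)
    y1 = y if y.ndim == 1 else y[:, 0]
    n = y1.size
    vals = [_r2_msd(p1, np.roll(y1, int(rng.integers(n // 4, 3 * n // 4))))[0]
            for _ in range(n_shuffles)]
    return float(np.quantile(vals, q))
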