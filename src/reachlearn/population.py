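"""Population structure: pairwise correlations and latent trajectories.

Two complementary views of ensemble coordination during the reach:

* the matrix of squared Pearson correlations between units' smoothed
  firing rates inside task windows, and the similarity of that matrix
  across training days (correlation of off-diagonal elements);
* single-trial latent trajectories from a Gaussian-process factor model
  (GPFA): square-rooted spike counts in 10 ms bins are modelled as a
  linear map of a low-dimensional latent state with per-latent
  squared-exponential temporal priors, fitted by EM.  Loadings are
  orthonormalized by SVD and dimensions ordered by variance explained;
  across-trial variance of the trajectories in the top dimensions is the
  learning diagnostic (it shrinks over days in success trials).

The factor model is y_t = C x_t + d + noise with diagonal noise R and
GP priors x_j ~ N(0, K_j), K_j the unit-variance squared-exponential
kernel with timescale tau_j (plus a small fixed jitter).  Because the
priors factor over latents and the likelihood over time, the posterior
precision has Kronecker structure K^-1 + (C' R^-1 C) (x) I_T, which the
E-step exploits.  The marginal log-likelihood is tracked every
iteration and must not decrease (a decrease raises ConvergenceError).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize_scalar

from .core import SpikeTrain

__all__ = [
    "CorrelationMatrix", "LatentModel", "TrajectorySet", "VarianceDiagnostics",
    "ConvergenceError", "pairwise_correlation", "matrix_similarity",
    "fit_latent_trajectories", "trajectory_variance",
]


class ConvergenceError(RuntimeError):
    """EM objective decreased; carries the iteration log."""

    def __init__(self, msg, log=None):
        super().__init__(msg)
        self.iteration_log = log or []


# --------------------------------------------------------------------------
# pairwise correlation structure

@dataclass
class CorrelationMatrix:
    """units x units squared Pearson correlations of smoothed rates."""

    r2: np.ndarray
    unit_ids: list
    window_definition: str = "food_provided_to_complete"

    def __post_init__(self):
        m = self.r2
        if m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices_from(self.r2, k=1)
        return self.r2[iu]


def pairwise_correlation(trains: list, windows: list, bin_s: float = 0.0125,
                         smooth_sigma_bins: float = 2.0) -> CorrelationMatrix:
    """Squared correlation of smoothed rates within task windows.

    Spike trains are binned at 12.5 ms inside each (t0, t1) window
    (typically food-provided to complete of success trials), smoothed
    with a Gaussian filter (sigma = 2 bins = 25 ms), concatenated across
    windows, and correlated pairwise.  Units with constant rate series
    get NaN rows/columns (undefined, never zero).
    """
    if len(trains) < 2:
        raise ValueError("need >= 2 units")
    if len(windows) < 5:
        raise ValueError("need >= 5 trial windows")
    series = []
    for tr in trains:
        segs = []
        for (t0, t1) in windows:
            n = max(int(round((t1 - t0) / bin_s)), 1)
            edges = t0 + bin_s * np.arange(n + 1)
            c = np.histogram(tr.times, bins=edges)[0].astype(float)
            segs.append(gaussian_filter1d(c, smooth_sigma_bins))
        series.append(np.concatenate(segs))
    x = np.array(series)
    n_u = x.shape[0]
    r2 = np.full((n_u, n_u), np.nan)
    sd = x.std(axis=1)
    ok = sd > 0
    if ok.any():
        c = np.corrcoef(x[ok])
        sub = np.square(np.atleast_2d(c))
        idx = np.flatnonzero(ok)
        r2[np.ix_(idx, idx)] = sub
    np.fill_diagonal(r2, np.where(ok, 1.0, np.nan))
    return CorrelationMatrix(r2=r2, unit_ids=[t.unit_id for t in trains])


def matrix_similarity(a: CorrelationMatrix, b: CorrelationMatrix) -> float:
    """Pearson correlation of the off-diagonal elements of two matrices.

    Both matrices must describe the same units in the same order.
    """
    if a.unit_ids != b.unit_ids:
        raise ValueError("unit set/ordering mismatch between matrices")
    x, y = a.off_diagonal(), b.off_diagonal()
    m = np.isfinite(x) & np.isfinite(y)
    if m.sum() < 3:
        return np.nan
    return float(np.corrcoef(x[m], y[m])[0, 1])


# --------------------------------------------------------------------------
# Gaussian-process factor analysis

_GP_JITTER = 1e-3   # fixed GP noise variance; signal variance is 1 - jitter


def _se_kernel(t: np.ndarray, tau: float) -> np.ndarray:
    d = t[:, None] - t[None, :]
    k = (1.0 - _GP_JITTER) * np.exp(-0.5 * (d / tau) ** 2)
    return k + _GP_JITTER * np.eye(t.size)


@dataclass
class LatentModel:
    """Fitted GPFA parameters plus the orthonormalized reporting basis."""

    loading: np.ndarray                # C, (units, latents)
    offset: np.ndarray                 # d, (units,)
    noise_var: np.ndarray              # diag R, (units,)
    timescales_s: np.ndarray           # per-latent GP timescale
    orth_basis: np.ndarray             # (units, latents), B^T B = I
    var_explained: np.ndarray          # per orthonormalized dimension share
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.noise_var <= 0):
            raise ValueError("noise variances must be > 0")
        btb = self.orth_basis.T @ self.orth_basis
        if not np.allclose(btb, np.eye(btb.shape[0]), atol=1e-8):
            raise ValueError("orthonormalized basis not orthonormal")


@dataclass
class TrajectorySet:
    """Per-trial latent paths in the top orthonormalized dimensions."""

    trajectories: np.ndarray           # (trials, dims, bins)
    times_s: np.ndarray
    trial_labels: list = field(default_factory=list)   # e.g. (day, outcome)


def fit_latent_trajectories(counts: np.ndarray, n_latent: int = 8,
                            bin_s: float = 0.01, n_report: int = 3,
                            em_iters: int = 25, tau_init_s: float = 0.1,
                            optimize_tau: bool = True, tol: float = 1e-6,
                            trial_labels=None, seed: int = 0):
    """Fit the GP factor model to square-rooted population counts.

    ``counts`` is (trials, units, bins) of non-overlapping 10 ms spike
    counts (square-rooting happens here).  Returns
    ``(LatentModel, TrajectorySet)`` with per-trial posterior-mean latent
    paths in the top ``n_report`` orthonormalized dimensions.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 3:
        raise ValueError("counts must be (trials, units, bins)")
    n_trials, q, t_len = counts.shape
    if q < 5:
        raise ValueError("need >= 5 units")
    if n_trials < 10:
        raise ValueError("need >= 10 trials")
    p = min(n_latent, q - 1)
    y = np.sqrt(counts)                             # (trials, q, T)
    times = bin_s * np.arange(t_len)

    # --- init from PCA of the concatenated observations
    flat = y.transpose(0, 2, 1).reshape(-1, q)      # (trials*T, q)
    d = flat.mean(axis=0)
    resid = flat - d
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    scale = s[:p] / np.sqrt(flat.shape[0])
    c_mat = vt[:p].T * scale[None, :]
    r_diag = np.maximum(resid.var(axis=0) - np.sum(c_mat**2, axis=1), 1e-3)
    taus = np.full(p, tau_init_s)

    y_centered = (y - d[None, :, None])
    log = []
    prev_ll = -np.inf

    for it in range(em_iters):
        # --- E-step
        k_chols = [cho_factor(_se_kernel(times, taus[j])) for j in range(p)]
        k_inv = np.zeros((p * t_len, p * t_len))
        logdet_k = 0.0
        for j in range(p):
            kinv_j = cho_solve(k_chols[j], np.eye(t_len))
            k_inv[j * t_len:(j + 1) * t_len, j * t_len:(j + 1) * t_len] = kinv_j
            logdet_k += 2.0 * np.sum(np.log(np.diag(k_chols[j][0])))
        a_mat = (c_mat.T / r_diag) @ c_mat          # (p, p)
        m_prec = k_inv.copy()
        for j in range(p):
            for j2 in range(p):
                idx1 = slice(j * t_len, (j + 1) * t_len)
                idx2 = slice(j2 * t_len, (j2 + 1) * t_len)
                m_prec[idx1, idx2] += a_mat[j, j2] * np.eye(t_len)
        m_chol = cho_factor(m_prec)
        sigma_post = cho_solve(m_chol, np.eye(p * t_len))
        logdet_m = 2.0 * np.sum(np.log(np.diag(m_chol[0])))

        # b = C^T R^-1 (y - d), latent-major (p*T) per trial
        proj = np.einsum("ij,njt->nit", (c_mat / r_diag[:, None]).T, y_centered)
        b = proj.reshape(n_trials, p * t_len)
        means = b @ sigma_post.T                    # (trials, p*T)

        # --- marginal log-likelihood (must not decrease)
        logdet_r = float(np.sum(np.log(r_diag))) * t_len
        quad_r = float(np.sum(y_centered**2 / r_diag[None, :, None]))
        quad_m = float(np.einsum("ni,ni->", means, b))
        ll = -0.5 * (n_trials * (q * t_len * np.log(2 * np.pi)
                                 + logdet_r + logdet_k + logdet_m)
                     + quad_r - quad_m)
        log.append({"iter": it, "loglik": ll})
        if ll < prev_ll - tol * abs(prev_ll):
            raise ConvergenceError(
                f"EM objective decreased at iteration {it}", log)
        if it > 0 and abs(ll - prev_ll) < tol * abs(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll

        # --- posterior moments per time point
        ex = means.reshape(n_trials, p, t_len)      # E[x]
        # Sigma_post diagonal blocks over time: cov(x_t) is (p, p) per t
        cov_t = np.empty((t_len, p, p))
        for t in range(t_len):
            idx = t + t_len * np.arange(p)
            cov_t[t] = sigma_post[np.ix_(idx, idx)]
        sum_ex = ex.sum(axis=(0, 2))                # (p,)
        sum_exx = (n_trials * cov_t.sum(axis=0)
                   + np.einsum("npt,nqt->pq", ex, ex))
        # --- M-step: [C d]
        nt = n_trials * t_len
        g11 = sum_exx
        g = np.zeros((p + 1, p + 1))
        g[:p, :p] = g11
        g[:p, p] = sum_ex
        g[p, :p] = sum_ex
        g[p, p] = nt
        h = np.zeros((q, p + 1))
        h[:, :p] = np.einsum("nit,npt->ip", y, ex)
        h[:, p] = y.sum(axis=(0, 2))
        cd = np.linalg.solve(g, h.T).T
        c_mat = cd[:, :p]
        d = cd[:, p]
        # R update
        yy = np.einsum("nit,nit->i", y, y)
        r_diag = np.maximum((yy - np.einsum("ik,ik->i", cd, h)) / nt, 1e-6)
        y_centered = y - d[None, :, None]

        # --- timescale M-step
        if optimize_tau:
            for j in range(p):
                idx = slice(j * t_len, (j + 1) * t_len)
                exx_j = (n_trials * sigma_post[idx, idx]
                         + ex[:, j, :].T @ ex[:, j, :])

                def _neg_q(log_tau):
                    k = _se_kernel(times, float(np.exp(log_tau)))
                    try:
                        cf = cho_factor(k)
                    except np.linalg.LinAlgError:
                        return np.inf
                    ld = 2.0 * np.sum(np.log(np.diag(cf[0])))
                    tr = np.trace(cho_solve(cf, exx_j))
                    return 0.5 * (n_trials * ld + tr)

                res = minimize_scalar(_neg_q, bounds=(np.log(2 * bin_s),
                                                      np.log(5.0)),
                                      method="bounded",
                                      options={"xatol": 1e-3})
                if res.success and res.fun <= _neg_q(np.log(taus[j])) + 1e-9:
                    taus[j] = float(np.exp(res.x))

    # --- final E-step latents under the converged parameters
    k_chols = [cho_factor(_se_kernel(times, taus[j])) for j in range(p)]
    k_inv = np.zeros((p * t_len, p * t_len))
    for j in range(p):
        k_inv[j * t_len:(j + 1) * t_len, j * t_len:(j + 1) * t_len] = \
            cho_solve(k_chols[j], np.eye(t_len))
    a_mat = (c_mat.T / r_diag) @ c_mat
    m_prec = k_inv
    for j in range(p):
        for j2 in range(p):
            m_prec[j * t_len:(j + 1) * t_len,
                   j2 * t_len:(j2 + 1) * t_len] += a_mat[j, j2] * np.eye(t_len)
    m_chol = cho_factor(m_prec)
    proj = np.einsum("ij,njt->nit", (c_mat / r_diag[:, None]).T,
                     y - d[None, :, None])
    means = cho_solve(m_chol, proj.reshape(n_trials, p * t_len).T).T
    ex = means.reshape(n_trials, p, t_len)

    # --- orthonormalize: C = U S V^T; x_orth = S V^T x
    u_c, s_c, vt_c = np.linalg.svd(c_mat, full_matrices=False)
    x_orth = np.einsum("kp,npt->nkt", s_c[:, None] * vt_c, ex)
    var_dim = x_orth.var(axis=(0, 2))
    share = var_dim / var_dim.sum() if var_dim.sum() > 0 else var_dim
    order = np.argsort(share)[::-1]
    x_orth = x_orth[:, order, :]
    share = share[order]
    basis = u_c[:, order]

    model = LatentModel(loading=c_mat, offset=d, noise_var=r_diag,
                        timescales_s=taus, orth_basis=basis,
                        var_explained=share, loglik_trace=log)
    traj = TrajectorySet(trajectories=x_orth[:, :n_report, :], times_s=times,
                         trial_labels=list(trial_labels)
                         if trial_labels is not None else [])
    return model, traj


# --------------------------------------------------------------------------
# across-trial trajectory variance

@dataclass
class VarianceDiagnostics:
    """Across-trial covariance diagonals of latent trajectories."""

    times_s: np.ndarray
    per_time_diag: np.ndarray          # (bins, dims)
    state_diags: dict                  # state name -> (dims,) diagonal
    total_variance: float              # time-integrated sum of diagonals
    skipped_groups: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.per_time_diag < -1e-12):
            raise ValueError("variances must be >= 0")


def trajectory_variance(ts: TrajectorySet, state_times: dict | None = None,
                        min_trials: int = 5) -> VarianceDiagnostics:
    """Across-trial variance of latent paths per time point and state.

    ``state_times`` maps state names (orient/grasp/complete...) to times
    on the trajectory time base; the covariance-ellipsoid diagonal at the
    nearest bin is reported per state.  The scalar summary integrates the
    total (summed-over-dimensions) variance over the window.
    """
    x = ts.trajectories                # (trials, dims, bins)
    skipped = []
    if x.shape[0] < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {x.shape[0]}")
    per_time = x.var(axis=0, ddof=1).T           # (bins, dims)
    dt = float(np.mean(np.diff(ts.times_s))) if ts.times_s.size > 1 else 1.0
    total = float(per_time.sum() * dt)
    state_diags = {}
    for name, t in (state_times or {}).items():
        i = int(np.argmin(np.abs(ts.times_s - t)))
        state_diags[name] = per_time[i]
    return VarianceDiagnostics(times_s=ts.times_s, per_time_diag=per_time,
                               state_diags=state_diags, total_variance=total,
                               skipped_groups=skipped)
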