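"""Spike-sorting quality metrics.

Units arrive pre-sorted as per-event waveforms plus labels; this module
computes the inclusion criteria used to accept a putative single unit
(SNR > 4, isolation distance >= 15, L-ratio <= 0.2, >= 99.5% of ISIs
above 2 ms) and the multi-cluster separation statistics (MANOVA F, J3,
Davies-Bouldin, Dunn) reported alongside them.

Isolation distance and L-ratio both use the Mahalanobis distance of
noise events from the cluster centre under the cluster's own covariance:
ID is the squared distance of the n-th closest noise event (n = cluster
size), L-ratio the chi-square tail mass of noise events near the cluster
normalized by cluster size.  Both are therefore invariant under affine
re-scaling of the feature space.

Undefined metrics (single cluster, too few noise events) are carried as
NaN, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import stats
from sklearn.metrics import davies_bouldin_score

from .core import SpikeTrain

__all__ = [
    "WaveformSet", "FeatureMatrix", "ClusterQuality",
    "extract_waveform_features", "compute_cluster_quality",
    "isolation_distance", "l_ratio", "dunn_index",
    "save_waveforms_h5", "load_waveforms_h5",
]


@dataclass
class WaveformSet:
    """Per-event spike waveforms of one unit on one day.

    ``events`` is (n_events, n_samples) voltage samples at
    ``sampling_rate`` (40 kHz for the recordings emulated here).
    ``noise_amplitude`` is the average noise level in the same units as
    the waveform, used for SNR.
    """

    unit_id: str
    day: int
    events: np.ndarray
    sampling_rate: float = 40_000.0
    noise_amplitude: float | None = None

    def __post_init__(self):
        self.events = np.atleast_2d(np.asarray(self.events, dtype=float))
        if self.events.shape[0] < 1:
            raise ValueError("WaveformSet needs at least one event")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_samples(self) -> int:
        return self.events.shape[1]

    def mean_waveform(self) -> np.ndarray:
        return self.events.mean(axis=0)

    def estimated_noise_amplitude(self) -> float:
        """2 x RMS of the residuals around the mean waveform.

        Used when no independent noise estimate accompanies the data.
        """
        resid = self.events - self.mean_waveform()
        return 2.0 * float(np.sqrt(np.mean(resid**2)))


@dataclass
class FeatureMatrix:
    """Per-event feature vectors with unit labels and a noise mask.

    Features follow the single-channel convention: energy, peak, valley
    and the leading principal-component scores (six features with the
    default three PCs).  ``labels`` assigns every row to a unit; rows
    where ``noise_mask`` is True belong to no accepted unit.
    """

    features: np.ndarray
    feature_names: list
    labels: np.ndarray
    noise_mask: np.ndarray | None = None
    degenerate_pcs: bool = False

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels must cover all feature rows")
        if not np.isfinite(self.features).all():
            raise ValueError("non-finite feature values")
        if self.noise_mask is None:
            self.noise_mask = np.zeros(self.features.shape[0], dtype=bool)


@dataclass
class ClusterQuality:
    """Quality metrics of one unit within its channel's event cloud."""

    snr: float = np.nan
    isolation_distance: float = np.nan
    l_ratio: float = np.nan
    refractory_ok_fraction: float = np.nan
    manova_f: float = np.nan
    manova_neglog_p: float = np.nan
    j3: float = np.nan
    neg_db: float = np.nan
    dunn: float = np.nan
    flags: list = field(default_factory=list)

    def passes_inclusion(self, snr_min=4.0, id_min=15.0, lratio_max=0.2,
                         refractory_min=0.995) -> bool:
        return (self.snr > snr_min and self.isolation_distance >= id_min
                and self.l_ratio <= lratio_max
                and self.refractory_ok_fraction >= refractory_min)


# --------------------------------------------------------------------------

def extract_waveform_features(wf: WaveformSet, n_pcs: int = 3) -> FeatureMatrix:
    """Energy, peak, valley and leading PC scores per spike event.

    Energy is the sum of squared samples, peak/valley the per-event max
    and min; PC scores come from the mean-centred event-by-sample matrix.
    All-identical events give a degenerate covariance: PC scores are then
    defined as zeros and the matrix is flagged.
    """
    ev = wf.events
    if n_pcs > wf.n_samples:
        raise ValueError("n_pcs exceeds sample count")
    energy = np.sum(ev**2, axis=1)
    peak = ev.max(axis=1)
    valley = ev.min(axis=1)
    centred = ev - ev.mean(axis=0, keepdims=True)
    degenerate = False
    if np.allclose(centred, 0.0) or wf.n_events < 2:
        scores = np.zeros((wf.n_events, n_pcs))
        degenerate = True
    else:
        # SVD of the centred matrix: scores = U * S
        u, s_, _ = np.linalg.svd(centred, full_matrices=False)
        k = min(n_pcs, s_.size)
        scores = np.zeros((wf.n_events, n_pcs))
        scores[:, :k] = u[:, :k] * s_[:k]
    feats = np.column_stack([energy, peak, valley, scores])
    names = ["energy", "peak", "valley"] + [f"pc{i+1}" for i in range(n_pcs)]
    return FeatureMatrix(features=feats, feature_names=names,
                         labels=np.full(wf.n_events, wf.unit_id, dtype=object),
                         degenerate_pcs=degenerate)


def _cluster_cov(x: np.ndarray, flags: list) -> np.ndarray:
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    # diagonal loading for singular within-cluster covariance
    if np.linalg.matrix_rank(cov) < cov.shape[0] or np.linalg.det(cov) <= 0:
        cov = cov + 1e-8 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        flags.append("covariance_regularized")
    return cov


def _mahalanobis_sq(points: np.ndarray, mean: np.ndarray,
                    cov: np.ndarray) -> np.ndarray:
    d = points - mean
    sol = np.linalg.solve(cov, d.T)
    return np.einsum("ij,ji->i", d, sol)


def isolation_distance(cluster: np.ndarray, noise: np.ndarray,
                       flags: list | None = None) -> float:
    """Squared Mahalanobis radius containing as many noise as cluster events.

    NaN when fewer noise events than cluster events exist (the ellipsoid
    is unbounded).
    """
    flags = [] if flags is None else flags
    n = cluster.shape[0]
    if noise.shape[0] < n:
        return np.nan
    cov = _cluster_cov(cluster, flags)
    d2 = _mahalanobis_sq(noise, cluster.mean(axis=0), cov)
    return float(np.sort(d2)[n - 1])


def l_ratio(cluster: np.ndarray, noise: np.ndarray,
            flags: list | None = None) -> float:
    """Chi-square tail mass of noise events near the cluster / cluster size."""
    flags = [] if flags is None else flags
    if noise.shape[0] == 0:
        return np.nan
    cov = _cluster_cov(cluster, flags)
    d2 = _mahalanobis_sq(noise, cluster.mean(axis=0), cov)
    df = cluster.shape[1]
    big_l = np.sum(1.0 - stats.chi2.cdf(d2, df))
    return float(big_l / cluster.shape[0])


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-centroid distance over max intra-cluster diameter."""
    uniq = np.unique(labels)
    if uniq.size < 2:
        return np.nan
    centroids = np.array([points[labels == u].mean(axis=0) for u in uniq])
    inter = np.inf
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            inter = min(inter, np.linalg.norm(centroids[i] - centroids[j]))
    diam = 0.0
    for u in uniq:
        p = points[labels == u]
        if p.shape[0] >= 2:
            from scipy.spatial.distance import pdist
            diam = max(diam, pdist(p).max())
    if diam == 0.0:
        return np.inf if inter > 0 else np.nan
    return float(inter / diam)


def _wilks_manova(points: np.ndarray, labels: np.ndarray):
    """Wilks' lambda one-way MANOVA -> (F via Rao's approximation, -log10 p)."""
    uniq = np.unique(labels)
    g = uniq.size
    n, p = points.shape
    if g < 2 or n - g < p:
        return np.nan, np.nan
    grand = points.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for u in uniq:
        grp = points[labels == u]
        d = grp - grp.mean(axis=0)
        w += d.T @ d
        m = (grp.mean(axis=0) - grand)[:, None]
        b += grp.shape[0] * (m @ m.T)
    det_w = np.linalg.det(w)
    det_t = np.linalg.det(w + b)
    if det_t <= 0:
        return np.nan, np.nan
    lam = det_w / det_t
    lam = min(max(lam, 1e-300), 1.0)
    q = g - 1
    # Rao's F approximation
    t_ = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if (p**2 + q**2 - 5) > 0 else 1.0
    df1 = p * q
    df2 = t_ * ((n - 1) - (p + g) / 2) - (p * q - 2) / 2
    if df2 <= 0:
        return np.nan, np.nan
    lam_t = lam ** (1.0 / t_)
    f = (1 - lam_t) / lam_t * df2 / df1
    p_val = stats.f.sf(f, df1, df2)
    neglog = -np.log10(max(p_val, 1e-300))
    return float(f), float(neglog)


def compute_cluster_quality(fm: FeatureMatrix, spikes: SpikeTrain | None = None,
                            wf: WaveformSet | None = None,
                            unit: object | None = None,
                            refractory_ms: float = 2.0) -> ClusterQuality:
    """All quality metrics for one unit within a channel's event cloud.

    ``fm`` holds every event on the channel (all units plus noise rows,
    marked by ``fm.noise_mask`` or label ``-1``); ``unit`` names the
    cluster of interest (default: the first non-noise label).  ``spikes``
    supplies the ISI-based refractory criterion and ``wf`` the SNR.
    """
    flags = []
    labels = fm.labels
    noise = fm.noise_mask | (labels == -1)
    uniq = [u for u in np.unique(labels[~noise])]
    if unit is None:
        if not uniq:
            raise ValueError("no non-noise cluster present")
        unit = uniq[0]
    cq = ClusterQuality()

    cl_pts = fm.features[(labels == unit) & ~noise]
    noise_pts = fm.features[noise]
    if cl_pts.shape[0] >= fm.features.shape[1] + 1 and noise_pts.shape[0] >= 1:
        cq.isolation_distance = isolation_distance(cl_pts, noise_pts, flags)
        cq.l_ratio = l_ratio(cl_pts, noise_pts, flags)
    else:
        flags.append("id_lratio_undefined")

    if wf is not None:
        noise_amp = wf.noise_amplitude or wf.estimated_noise_amplitude()
        if noise_amp > 0:
            cq.snr = float(np.ptp(wf.mean_waveform()) / noise_amp)

    if spikes is not None and spikes.n_spikes >= 2:
        isi_ms = spikes.isi() * 1000.0
        cq.refractory_ok_fraction = float(np.mean(isi_ms > refractory_ms))

    # multi-cluster statistics on the first two PCs
    if len(uniq) >= 2:
        pc_cols = [i for i, nm in enumerate(fm.feature_names)
                   if nm.startswith("pc")][:2]
        if len(pc_cols) < 2:
            pc_cols = [0, 1]
        pts = fm.features[~noise][:, pc_cols]
        labs = labels[~noise]
        cq.manova_f, cq.manova_neglog_p = _wilks_manova(pts, labs)
        grand = pts.mean(axis=0)
        w = sum(float(np.sum((pts[labs == u] - pts[labs == u].mean(axis=0))**2))
                for u in uniq)
        b = sum(pts[labs == u].shape[0]
                * float(np.sum((pts[labs == u].mean(axis=0) - grand)**2))
                for u in uniq)
        cq.j3 = (b / w / len(uniq)) if w > 0 else np.nan
        labs_int = np.searchsorted(np.array(sorted(map(str, uniq))),
                                   labs.astype(str))
        try:
            cq.neg_db = -float(davies_bouldin_score(pts, labs_int))
        except ValueError:
            cq.neg_db = np.nan
        cq.dunn = dunn_index(pts, labs)
    else:
        flags.append("single_cluster")
    cq.flags = flags
    return cq


# --------------------------------------------------------------------------
# HDF5 interface: group per unit/day with an `events` dataset

def save_waveforms_h5(path, waveform_sets: list):
    with h5py.File(path, "w") as f:
        for ws in waveform_sets:
            g = f.create_group(f"{ws.unit_id}/day{ws.day}")
            g.create_dataset("events", data=ws.events)
            g.attrs["sampling_rate_hz"] = ws.sampling_rate
            if ws.noise_amplitude is not None:
                g.attrs["noise_amplitude"] = ws.noise_amplitude


def load_waveforms_h5(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        for uid in f:
            for dkey in f[uid]:
                g = f[uid][dkey]
                out.append(WaveformSet(
                    unit_id=uid, day=int(dkey.removeprefix("day")),
                    events=g["events"][()],
                    sampling_rate=float(g.attrs["sampling_rate_hz"]),
                    noise_amplitude=float(g.attrs["noise_amplitude"])
                    if "noise_amplitude" in g.attrs else None))
    return out
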