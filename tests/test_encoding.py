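"""PETH, time-lagged MI (with joint-histogram oracle), typing, Fano."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

import reachlearn as rl
from reachlearn import encoding as enc, synth
from reachlearn.core import InsufficientDataError, SpikeTrain


def _poisson_train(rng, rate, duration):
    n = rng.poisson(rate * duration)
    return SpikeTrain("u", np.sort(rng.uniform(0, duration, n)), 0.0, duration)


def _direct_mi_bits(x, y):
    """Independent oracle: MI from the joint histogram by definition."""
    xs, ys = np.unique(x), np.unique(y)
    n = len(x)
    mi = 0.0
    for xv in xs:
        for yv in ys:
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0:
                mi += pxy * np.log2(pxy / (np.mean(x == xv) * np.mean(y == yv)))
    return mi


# -- PETH -------------------------------------------------------------------

def test_peth_poisson_z_rarely_extreme(rng):
    tr = _poisson_train(rng, 8.0, 1200.0)
    events = np.arange(10.0, 1190.0, 11.0)[:100]
    p = enc.compute_peth(tr, events)
    frac = np.mean(np.abs(p.z) > 3)
    assert frac < 0.01


def test_peth_rate_step_gives_positive_z(rng):
    base = _poisson_train(rng, 4.0, 600.0)
    events = np.arange(10.0, 590.0, 10.0)
    extra = np.concatenate([ev + np.sort(rng.uniform(0, 0.5, 6))
                            for ev in events])
    tr = SpikeTrain("u", np.sort(np.concatenate([base.times, extra])), 0.0, 600.0)
    p = enc.compute_peth(tr, events, window=(-6.0, 1.0))
    post = p.z[(p.bin_centers_s > 0.05) & (p.bin_centers_s < 0.45)]
    assert post.mean() > 3


def test_peth_zero_spikes_gives_undefined_z():
    tr = SpikeTrain("u", np.zeros(0), 0.0, 100.0)
    p = enc.compute_peth(tr, np.array([50.0]))
    assert np.all(p.counts == 0)
    assert np.all(np.isnan(p.z))


def test_peth_drops_out_of_span_events(rng):
    tr = _poisson_train(rng, 5.0, 100.0)
    p = enc.compute_peth(tr, np.array([1.0, 50.0]), window=(-6.0, 1.0))
    assert p.n_dropped == 1


def test_time_until_divergence_flat_and_step(rng):
    flat = _poisson_train(rng, 10.0, 1500.0)
    events = np.arange(10.0, 1490.0, 12.0)[:120]
    p = enc.compute_peth(flat, events)
    assert enc.time_until_divergence(p, seed=0) is None

    # strong rate step at +100 ms after the event
    base = _poisson_train(rng, 3.0, 1500.0)
    extra = np.concatenate([ev + 0.1 + np.sort(rng.uniform(0, 0.4, 10))
                            for ev in events])
    tr = SpikeTrain("u", np.sort(np.concatenate([base.times, extra])),
                    0.0, 1500.0)
    p2 = enc.compute_peth(tr, events)
    tud = enc.time_until_divergence(p2, seed=0)
    assert tud is not None
    assert 0.0875 <= tud <= 0.1125

    few = enc.compute_peth(tr, events[:5])
    with pytest.raises(InsufficientDataError):
        enc.time_until_divergence(few, seed=0)


# -- mutual information -----------------------------------------------------

def test_plug_in_mi_matches_joint_histogram_oracle(rng):
    counts = rng.integers(0, 4, 500)
    codes = rng.integers(0, 8, 500)
    got = enc.binned_mi_profile(counts, codes, lags_ms=np.array([0.0]))[0]
    assert got == pytest.approx(_direct_mi_bits(counts, codes), abs=1e-12)


def test_mi_symmetry_at_zero_lag(rng):
    a = rng.integers(0, 3, 400)
    b = rng.integers(0, 5, 400)
    assert enc.binned_mi_profile(a, b, np.array([0.0]))[0] == pytest.approx(
        enc.binned_mi_profile(b, a, np.array([0.0]))[0], abs=1e-12)


def test_deterministic_binary_coupling_gives_one_bit(rng):
    x = rng.integers(0, 2, 1000)
    got = enc.binned_mi_profile(x, x, np.array([0.0]))[0]
    assert got == pytest.approx(1.0, abs=0.01)


def test_mi_invariant_under_monotone_velocity_transform(rng):
    """Quantile binning makes MI exactly invariant to monotone maps."""
    t = 16000
    v = np.abs(gaussian_filter1d(rng.normal(0, 1, t), 5))
    counts = rng.poisson(0.1 + 0.5 * v / v.max())
    tr = SpikeTrain("u", np.repeat(np.arange(t) * enc.BIN_S, counts),
                    0.0, t * enc.BIN_S)
    p1 = enc.time_lagged_mi(tr, v)
    p2 = enc.time_lagged_mi(tr, np.exp(3 * v))   # strictly monotone map
    np.testing.assert_allclose(p1.mi_bits, p2.mi_bits, atol=1e-12)


def test_constant_velocity_degenerate(rng):
    tr = _poisson_train(rng, 5.0, 120.0)
    prof = enc.time_lagged_mi(tr, np.ones(int(120 / enc.BIN_S)))
    assert prof.degenerate
    assert np.all(prof.mi_bits == 0.0)


def test_short_span_raises(rng):
    tr = _poisson_train(rng, 5.0, 30.0)
    with pytest.raises(InsufficientDataError):
        enc.time_lagged_mi(tr, np.ones(100))


def test_planted_lag_recovered(rng):
    """A 150 ms velocity-following unit has tau_opt at +150 ms."""
    t = np.arange(48000) / 80.0
    v = np.clip(gaussian_filter1d(rng.normal(0, 1, t.size), 8), 0, None) * 10
    g = v / v.max()
    lam_max = 13.0
    cand = np.sort(rng.uniform(0, t[-1], rng.poisson(lam_max * t[-1])))
    lam = 5.0 + 8.0 * np.interp(cand + 0.150, t, g, left=0, right=0)
    st = SpikeTrain("u", cand[rng.random(cand.size) < lam / lam_max], 0.0, t[-1])
    prof = enc.time_lagged_mi(st, v, vel_times=t)
    assert abs(prof.tau_opt_ms - 150.0) <= 12.5
    assert prof.lags_ms.size == 81


def test_mi_grid_is_81_lags_spanning_500ms():
    assert enc.LAG_GRID_MS.size == 81
    assert enc.LAG_GRID_MS[0] == -500.0 and enc.LAG_GRID_MS[-1] == 500.0
    assert np.allclose(np.diff(enc.LAG_GRID_MS), 12.5)


# -- bootstrap significance -------------------------------------------------

def test_mi_significance_validates_n_boot(rng):
    tr = _poisson_train(rng, 5.0, 120.0)
    with pytest.raises(ValueError):
        enc.mi_significance(tr, np.ones(9600), n_boot=100)


def test_strong_coupling_is_significant(rng):
    t = np.arange(24000) / 80.0
    v = np.clip(gaussian_filter1d(rng.normal(0, 1, t.size), 8), 0, None) * 10
    g = v / np.quantile(v, 0.95)
    lam_max = 16.0
    cand = np.sort(rng.uniform(0, t[-1], rng.poisson(lam_max * t[-1])))
    lam = 4.0 + 12.0 * np.clip(np.interp(cand, t, g), 0, 1)
    st = SpikeTrain("u", cand[rng.random(cand.size) < lam / lam_max], 0.0, t[-1])
    prof = enc.mi_significance(st, v, vel_times=t, n_boot=400, seed=0)
    assert prof.significant
    assert prof.p_value <= 1.0 / 400


def test_null_kernel_matches_python_resampling(rng):
    """The sparse numba null agrees with a brute-force resampling null."""
    t_len = 5600
    counts = rng.poisson(0.12, t_len)
    codes = rng.integers(0, 4, t_len)
    tr = SpikeTrain("u", np.repeat(np.arange(t_len) * enc.BIN_S, counts),
                    0.0, t_len * enc.BIN_S)
    lags = np.arange(-100.0, 100.1, 25.0)
    prof = enc.mi_significance(tr, codes.astype(float), n_boot=400,
                               lags_ms=lags, seed=1)
    # brute force: resample count bins, recompute the profile max
    null = []
    for _ in range(400):
        resampled = counts[rng.integers(0, t_len, t_len)]
        null.append(enc.binned_mi_profile(resampled, codes, lags).max())
    brute_thr = np.quantile(null, 0.99)
    assert prof.threshold == pytest.approx(brute_thr, rel=0.35)


def test_circular_null_alternative(rng):
    tr = _poisson_train(rng, 6.0, 120.0)
    v = np.abs(gaussian_filter1d(rng.normal(0, 1, int(120 / enc.BIN_S)), 5))
    prof = enc.mi_significance(tr, v, n_boot=250, seed=0,
                               null_method="circular")
    assert np.isfinite(prof.threshold)


# -- warp control ------------------------------------------------------------

def test_identity_warp_preserves_profile(rng):
    n_tr, t_len = 12, 160
    counts = [rng.poisson(0.3, t_len) for _ in range(n_tr)]
    vels = [np.abs(gaussian_filter1d(rng.normal(0, 1, t_len), 4))
            for _ in range(n_tr)]
    ident = np.column_stack([np.arange(t_len), np.arange(t_len)])
    lags = np.arange(-100.0, 100.1, 12.5)
    warped = enc.warp_controlled_mi(counts, vels, [ident] * n_tr, lags_ms=lags)
    codes, _ = enc._discretize_velocity(np.concatenate(vels))
    direct = enc.binned_mi_profile(np.concatenate(counts), codes, lags)
    np.testing.assert_allclose(warped.mi_bits, direct, atol=1e-12)


def test_dilated_trial_recovers_lag_after_warping(rng):
    """Warping a 2x time-dilated trial restores the undilated tau_opt."""
    from reachlearn import behavior
    t_len = 400
    v = np.abs(gaussian_filter1d(rng.normal(0, 1, t_len), 6)) * 5
    k = 8   # true lag in bins (100 ms)
    lam = 0.15 + 1.2 * np.roll(v, k) / v.max()
    counts = rng.poisson(lam)
    # dilated trial: every sample doubled
    v2 = np.repeat(v, 2)
    counts2 = np.repeat(counts, 2)
    warp = behavior.dtw_deviation(v2.reshape(-1, 1), v.reshape(-1, 1)).path
    lags = np.arange(-250.0, 250.1, 12.5)
    ref_prof = enc.warp_controlled_mi([counts], [v],
                                      [np.column_stack([np.arange(t_len)] * 2)],
                                      lags_ms=lags)
    warped = enc.warp_controlled_mi([counts2 / 2.0], [v2], [warp], lags_ms=lags)
    assert abs(warped.tau_opt_ms - ref_prof.tau_opt_ms) <= 12.5


def test_warp_outside_window_raises(rng):
    bad = np.column_stack([np.arange(10), np.arange(10)])
    with pytest.raises(ValueError):
        enc.warp_controlled_mi([np.zeros(5)], [np.zeros(5)], [bad])


# -- cell typing ------------------------------------------------------------

def test_pn_in_separation_and_scale_invariance(rng):
    n = 40
    wide = np.column_stack([rng.normal(0.5, 0.03, n),
                            rng.normal(0.5, 0.05, n),
                            rng.normal(7, 1.5, n)])
    narrow = np.column_stack([rng.normal(0.2, 0.03, n // 2),
                              rng.normal(0.9, 0.05, n // 2),
                              rng.normal(16, 2.0, n // 2)])
    feats = np.vstack([wide, narrow])
    truth = np.concatenate([np.zeros(n, bool), np.ones(n // 2, bool)])
    got = enc.classify_pn_in(feats, seed=0)
    assert np.mean(got == truth) >= 0.95
    scaled = feats * np.array([1000.0, 1.0, 0.001])
    np.testing.assert_array_equal(enc.classify_pn_in(scaled, seed=0), got)


def test_pn_in_validates_input():
    with pytest.raises(InsufficientDataError):
        enc.classify_pn_in(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        enc.classify_pn_in(np.ones((10, 3)))


def test_cluster_im_types_archetypes_and_flat(rng):
    days = 7
    stable = np.tile([0.5], (8, days)) + rng.normal(0, 0.02, (8, days))
    ramp = np.linspace(0.02, 0.5, days)[None, :] * np.ones((8, 1)) \
        + rng.normal(0, 0.02, (8, days))
    flat = np.abs(rng.normal(0.02, 0.005, (8, days)))
    im = np.vstack([stable, ramp, flat])
    sig = np.vstack([np.ones((8, days), bool),
                     np.repeat([[False] + [True] * (days - 1)], 8, axis=0),
                     np.zeros((8, days), bool)])
    tau = np.vstack([np.full((8, days), 150.0),
                     np.linspace(225, 141, days)[None, :] * np.ones((8, 1)),
                     rng.uniform(-400, 400, (8, days))])
    labels = enc.cluster_im_types(im, tau, sig)
    truth = np.repeat([1, 2, 3], 8)
    assert np.mean(labels.types == truth) >= 0.9
    assert labels.tau_change_ms[2] == pytest.approx(-84.0, abs=1.0)

    all_flat_sig = np.zeros((12, days), bool)
    labels2 = enc.cluster_im_types(np.abs(rng.normal(0.02, 0.005, (12, days))),
                                   rng.uniform(-400, 400, (12, days)),
                                   all_flat_sig)
    assert np.all(labels2.types == 3)


def test_cluster_im_types_clips_k_range():
    rng = np.random.default_rng(0)
    im = rng.random((5, 7))
    labels = enc.cluster_im_types(im, im, im > 0.5, k_range=range(2, 9))
    assert "k_range_clipped" in labels.flags


# -- Fano factor ------------------------------------------------------------

def test_fano_poisson_near_one(rng):
    counts = [rng.poisson(2.5, (200, 30)) for _ in range(30)]
    res = enc.mean_matched_fano(counts, times_s=np.linspace(-1, 1, 30))
    assert np.nanmax(np.abs(res.fano_raw - 1)) < 0.1


def test_fano_deterministic_counts_zero():
    counts = [np.tile(np.arange(1, 11), (20, 1)) for _ in range(5)]
    res = enc.mean_matched_fano(counts)
    assert np.allclose(res.fano_raw, 0.0)


def test_fano_all_zero_undefined():
    res = enc.mean_matched_fano([np.zeros((10, 5)) for _ in range(4)])
    assert np.all(np.isnan(res.fano_raw))


def test_fano_overdispersion_follows_total_variance_law(rng):
    """Gamma-mixed Poisson: var = mean + CV^2 * mean^2 (law of total
    variance); the regression slope exceeds 1 accordingly."""
    cv2 = 0.5
    mean_rate = 3.0
    shape = 1 / cv2
    lam = rng.gamma(shape, mean_rate / shape, (400, 20, 25))
    counts = [rng.poisson(lam[:, u, :]) for u in range(20)]
    res = enc.mean_matched_fano(counts, times_s=np.linspace(-1, 1, 25))
    expected_ff = 1 + cv2 * mean_rate
    assert np.nanmean(res.fano_raw) == pytest.approx(expected_ff, rel=0.15)


def test_mean_matching_never_adds_points(rng):
    counts = [rng.poisson(rng.uniform(0.5, 4.0), (50, 15)) for _ in range(12)]
    res = enc.mean_matched_fano(counts)
    assert np.all(res.n_points_per_bin <= len(counts))


def test_sliding_counts_match_direct_histogram(rng):
    tr = _poisson_train(rng, 20.0, 50.0)
    events = np.array([10.0, 25.0, 40.0])
    counts, centers = enc.sliding_spike_counts(tr, events)
    for i, ev in enumerate(events):
        for j, c in enumerate(centers):
            s0 = ev + c - 0.025
            direct = np.count_nonzero((tr.times >= s0) & (tr.times < s0 + 0.05))
            assert counts[i, j] == direct
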