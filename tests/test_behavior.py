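"""Kinematics, DTW against an exhaustive-path oracle, and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import reachlearn as rl
from reachlearn import behavior, synth
from reachlearn.core import KinematicTrace


def _brute_force_dtw(a, b):
    """Exhaustive enumeration of all monotone warping paths (oracle)."""
    a = np.atleast_2d(np.asarray(a, float).reshape(len(a), -1))
    b = np.atleast_2d(np.asarray(b, float).reshape(len(b), -1))
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += np.linalg.norm(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return best[0]


# -- velocity ---------------------------------------------------------------

def test_velocity_trivial_and_analytic_cases():
    t = np.arange(160) / 80.0
    const = KinematicTrace(t, np.ones_like(t), np.ones_like(t))
    assert np.allclose(behavior.compute_velocity(const), 0.0)

    linear = KinematicTrace(t, t.copy(), np.zeros_like(t))
    assert np.allclose(behavior.compute_velocity(linear), 1.0)

    r, w = 2.0, 3.0
    circ = KinematicTrace(t, r * np.cos(w * t), r * np.sin(w * t))
    v = behavior.compute_velocity(circ)
    assert np.allclose(v[2:-2], r * w, rtol=0.01)


def test_velocity_needs_two_samples():
    tr = KinematicTrace(np.array([0.0]), np.array([0.0]), np.array([0.0]))
    with pytest.raises(ValueError):
        behavior.compute_velocity(tr)


def test_nonuniform_sampling_rejected():
    with pytest.raises(ValueError):
        KinematicTrace(np.array([0.0, 0.01, 0.5]), np.zeros(3), np.zeros(3))


# -- reference trajectory ---------------------------------------------------

def _trace(xy):
    xy = np.asarray(xy, float)
    t = np.arange(len(xy)) / 80.0
    return KinematicTrace(t, xy[:, 0], xy[:, 1])


def test_reference_of_identical_trials_equals_input():
    path = np.column_stack([np.linspace(0, 1, 30), np.sin(np.linspace(0, 3, 30))])
    trials = [_trace(path) for _ in range(5)]
    ref = behavior.build_reference_trajectory(trials, n=5, seed=0)
    np.testing.assert_allclose(ref.positions(), path, atol=1e-12)


def test_reference_of_mirror_trials_is_midline():
    base = np.column_stack([np.linspace(0, 1, 30), np.linspace(0, 2, 30)])
    up = base + np.array([0.0, 1.0])
    dn = base - np.array([0.0, 1.0])
    ref = behavior.build_reference_trajectory([_trace(up), _trace(dn)],
                                              n=2, seed=0)
    np.testing.assert_allclose(ref.positions(), base, atol=1e-12)


def test_reference_requires_enough_trials():
    with pytest.raises(ValueError):
        behavior.build_reference_trajectory([_trace(np.zeros((5, 2)))], n=50)


# -- DTW --------------------------------------------------------------------

def test_dtw_identity_is_zero():
    path = np.column_stack([np.linspace(0, 1, 20), np.cos(np.linspace(0, 2, 20))])
    dev = behavior.dtw_deviation(_trace(path), _trace(path))
    assert dev.cumulative_distance == 0.0
    assert tuple(dev.path[0]) == (0, 0)
    assert tuple(dev.path[-1]) == (19, 19)


def test_dtw_simple_sequences_match_enumeration():
    got = behavior.dtw_deviation(np.array([0.0, 1.0, 2.0]),
                                 np.array([0.0, 2.0]))
    assert got.cumulative_distance == pytest.approx(1.0)
    assert got.cumulative_distance == pytest.approx(
        _brute_force_dtw([0.0, 1.0, 2.0], [0.0, 2.0]))


def test_dtw_matches_exhaustive_oracle_on_short_sequences(rng):
    """DP solution equals exhaustive path enumeration for lengths <= 6."""
    for _ in range(25):
        n, m = rng.integers(1, 7), rng.integers(1, 7)
        a = rng.normal(0, 1, (n, 2))
        b = rng.normal(0, 1, (m, 2))
        got = behavior.dtw_deviation(a, b).cumulative_distance
        assert got == pytest.approx(_brute_force_dtw(a, b), rel=1e-10)


def test_dtw_symmetry_and_diagonal_bound(rng):
    a = rng.normal(0, 1, (12, 2))
    b = rng.normal(0, 1, (12, 2))
    d_ab = behavior.dtw_deviation(a, b).cumulative_distance
    d_ba = behavior.dtw_deviation(b, a).cumulative_distance
    assert d_ab == pytest.approx(d_ba, rel=1e-12)
    pointwise = float(np.linalg.norm(a - b, axis=1).sum())
    assert d_ab <= pointwise + 1e-12
    assert d_ab >= 0.0


def test_dtw_warp_path_monotone(rng):
    a = rng.normal(0, 1, (10, 2))
    b = rng.normal(0, 1, (14, 2))
    path = behavior.dtw_deviation(a, b).path
    assert np.all(np.diff(path, axis=0) >= 0)
    assert np.all(np.diff(path, axis=0).sum(axis=1) >= 1)


def test_dtw_empty_input_raises():
    with pytest.raises(ValueError):
        behavior.dtw_deviation(np.zeros((0, 2)), np.ones((3, 2)))


# -- summaries --------------------------------------------------------------

def _mk_table(delays, outcomes):
    rows = []
    t = 0.0
    for k, (d, oc) in enumerate(zip(delays, outcomes)):
        rows.append({
            "trial": k, "day": 0, "session": 0, "food_provided_time": t,
            "orient_time": t + d, "advance_time": t + d + 0.1,
            "extend_time": t + d + 0.2, "grasp_time": t + d + 0.3,
            "retract_time": t + d + 0.4, "complete_time": t + d + 0.5,
            "outcome": oc})
        t += 10.0
    return pd.DataFrame(rows)


def test_summary_all_success_and_delay_stats():
    tt = _mk_table([1.0, 3.0], ["first_success"] * 2)
    summ = behavior.summarize_behavior(tt)
    row = summ.table.iloc[0]
    assert row["success_rate_pct"] == 100.0
    assert row["delay_mean_s"] == pytest.approx(2.0)
    assert row["delay_sd_s"] == pytest.approx(np.sqrt(2.0))
    assert summ.conserved_counts()


def test_summary_excludes_incomplete_trials_and_conserves_counts():
    tt = _mk_table([1.0] * 4, ["first_success", "first_failure",
                               "other", "first_success"])
    tt.loc[2, "grasp_time"] = np.nan
    summ = behavior.summarize_behavior(tt)
    assert summ.n_excluded == 1
    row = summ.table.iloc[0]
    assert row["n_trials"] + summ.n_excluded == 4
    assert summ.conserved_counts()


def test_summary_recovers_generator_schedule():
    """Session success rates and delays follow the configured skill."""
    cfg = rl.SimConfig(trials_per_session=60, rng_seed=21)
    _, t_early = synth.generate_session_kinematics(cfg, 0, 0)
    _, t_late = synth.generate_session_kinematics(cfg, 6, 5)
    s_early = behavior.summarize_behavior(t_early).table.iloc[0]
    s_late = behavior.summarize_behavior(t_late).table.iloc[0]
    assert s_late["success_rate_pct"] > s_early["success_rate_pct"]
    assert s_late["delay_mean_s"] < s_early["delay_mean_s"]
    assert s_late["extension_dur_mean_s"] < s_early["extension_dur_mean_s"]


# -- matched-trial selection -------------------------------------------------

def test_matched_selection_homogeneous_pool_and_outlier():
    devs = np.full(40, 2.0)
    idx, _ = behavior.select_trajectory_matched_trials(
        [None] * 40, None, n=30, seed=1, deviations=devs)
    assert idx.size == 30

    devs2 = devs.copy()
    devs2[7] = 50.0
    idx2, _ = behavior.select_trajectory_matched_trials(
        [None] * 40, None, n=30, seed=1, deviations=devs2)
    assert 7 not in idx2


def test_matched_selection_reproducible_and_bounded():
    devs = np.random.default_rng(3).normal(5, 1, 60)
    i1, _ = behavior.select_trajectory_matched_trials(
        [None] * 60, None, n=20, seed=9, deviations=devs)
    i2, _ = behavior.select_trajectory_matched_trials(
        [None] * 60, None, n=20, seed=9, deviations=devs)
    np.testing.assert_array_equal(i1, i2)
    with pytest.raises(ValueError):
        behavior.select_trajectory_matched_trials(
            [None] * 60, None, n=60, seed=9, deviations=devs)


def test_deviation_decreases_with_training():
    """DTW deviation from the expert reference falls across days."""
    cfg = rl.SimConfig(trials_per_session=30, rng_seed=17)
    kin7, tt7 = synth.generate_session_kinematics(cfg, 6, 5)
    succ7 = tt7[tt7["outcome"] == "first_success"]
    ref_pool = behavior.extract_trial_traces(kin7, succ7)
    ref = behavior.build_reference_trajectory(
        ref_pool, n=min(10, len(ref_pool)), seed=0)
    day_means = []
    for d in range(0, 7, 2):
        kin, tt = synth.generate_session_kinematics(cfg, d, 0)
        trials = behavior.extract_trial_traces(kin, tt)
        devs = [behavior.dtw_deviation(t, ref).cumulative_distance
                for t in trials]
        day_means.append(np.mean(devs))
    rho = stats.spearmanr(np.arange(len(day_means)), day_means).statistic
    assert rho < 0
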