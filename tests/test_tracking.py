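"""Similarity scores, classifier calibration, and tracking decisions."""

import numpy as np
import pytest

import reachlearn as rl
from reachlearn import synth, tracking
from reachlearn.core import InsufficientDataError, SpikeTrain
from reachlearn.quality import WaveformSet


def _scores(rng, mu, n, cov=None):
    cov = np.eye(2) * 0.04 if cov is None else cov
    x = rng.multivariate_normal(mu, cov, n)
    return [tracking.SimilarityScores(
        max_r_z=a, d_pamp=abs(rng.normal(0.1, 0.03)),
        isih_div=abs(b), acorr_div=abs(rng.normal(0.3, 0.05)))
        for a, b in x]


def test_symmetrized_kl_direct_formula_oracle():
    """Jeffreys average of KL(p||q) and KL(q||p) for two 2-bin histograms.

    For p=(1/2,1/2), q=(1/4,3/4): KL(p||q)=0.20752, KL(q||p)=0.18872
    bits, so the symmetrized divergence is 0.19812 (direct computation).
    """
    p, q = np.array([0.5, 0.5]), np.array([0.25, 0.75])
    kl_pq = np.sum(p * np.log2(p / q))
    kl_qp = np.sum(q * np.log2(q / p))
    expected = 0.5 * (kl_pq + kl_qp)
    assert expected == pytest.approx(0.198120, abs=1e-5)
    assert tracking.symmetrized_kl(p, q) == pytest.approx(expected, abs=1e-6)
    assert tracking.symmetrized_kl(q, p) == tracking.symmetrized_kl(p, q)


def test_identical_unit_scores_are_degenerate(day0_session):
    wf, tr = day0_session["wfs"][0], day0_session["trains"][0]
    s = tracking.compute_similarity_scores((wf, tr), (wf, tr))
    assert s.d_pamp == 0.0
    assert s.isih_div == pytest.approx(0.0, abs=1e-12)
    assert s.acorr_div == pytest.approx(0.0, abs=1e-12)
    assert "r_clipped" in s.flags
    assert s.max_r_z == pytest.approx(np.arctanh(1 - 1e-12))


def test_shifted_waveform_found_at_two_sample_shift():
    """A 2-sample delayed copy is matched exactly at |shift| = 2."""
    t = np.linspace(0, 1, 32)
    a = -np.exp(-0.5 * ((t - 0.4) / 0.06) ** 2)
    b = np.roll(a, 2)       # delayed copy
    r, shift = tracking._max_shifted_correlation(a, b)
    assert abs(shift) == 2
    assert r == pytest.approx(1.0, abs=1e-12)


def test_too_few_spikes_raises(day0_session):
    wf = day0_session["wfs"][0]
    tiny = SpikeTrain("u", np.linspace(0, 1, 10), 0.0, 1.0)
    with pytest.raises(InsufficientDataError):
        tracking.compute_similarity_scores((wf, tiny), (wf, tiny))


def test_classifier_calibration_on_planted_gaussians(rng):
    """Held-out negative error matches the 5% target within binomial CI."""
    pos = _scores(rng, [3.0, 0.2], 1000)
    neg = _scores(rng, [1.0, 1.5], 1000)
    model = tracking.fit_tracking_classifier(pos[:500], neg[:500])
    err = float(np.mean(model.discriminant(neg[500:]) > 0))
    # the held-out error carries binomial noise from both the estimated
    # decision threshold (500 training negatives) and the 500 test draws:
    # 3 x the combined standard error
    se = np.sqrt(0.05 * 0.95 * (1 / 500 + 1 / 500))
    assert abs(err - 0.05) < 3 * se
    assert abs(model.selection["calibration_achieved"] - 0.05) <= 0.005


def test_indistinguishable_classes_give_chance_accuracy(rng):
    pos = _scores(rng, [1.0, 1.0], 400)
    neg = _scores(rng, [1.0, 1.0], 400)
    try:
        model = tracking.fit_tracking_classifier(pos[:200], neg[:200])
    except InsufficientDataError:
        return   # refusing to fit indistinguishable classes is acceptable
    acc = 0.5 * (np.mean(model.discriminant(pos[200:]) > 0)
                 + np.mean(model.discriminant(neg[200:]) <= 0))
    assert abs(acc - 0.5) < 0.12


def test_quadratic_decision_matches_bayes_density_ratio(rng):
    """The model's call on raw scores equals a brute-force Bayes rule.

    The oracle transforms the grid independently (log1p for divergences,
    pooled standardization) and thresholds the Gaussian density ratio.
    """
    from scipy.stats import multivariate_normal
    pos = _scores(rng, [3.0, 0.2], 400)
    neg = _scores(rng, [1.0, 1.5], 400)
    model = tracking.fit_tracking_classifier(pos, neg, target_error=0.05)
    assert "isih_div" in model.feature_pair and "max_r_z" in model.feature_pair
    zs = np.linspace(-1, 5, 60)
    ds = np.linspace(0, 4, 60)
    gz, gd = np.meshgrid(zs, ds)
    scores = [tracking.SimilarityScores(max_r_z=a, d_pamp=0.1, isih_div=b,
                                        acorr_div=0.3)
              for a, b in zip(gz.ravel(), gd.ravel())]
    got = model.discriminant(scores) > 0
    # independent oracle path
    raw = np.column_stack([gz.ravel(), np.log1p(gd.ravel())])
    if model.feature_pair == ("isih_div", "max_r_z"):
        raw = raw[:, ::-1]
    std = (raw - model.scale_mean) / model.scale_sd
    lp = multivariate_normal(model.pos_mean, model.pos_cov).logpdf(std)
    ln = multivariate_normal(model.neg_mean, model.neg_cov).logpdf(std)
    oracle = (lp - ln + model.offset) > 0
    assert np.mean(got == oracle) > 0.999


def test_track_decision_rules(rng):
    pos = _scores(rng, [3.0, 0.2], 400)
    neg = _scores(rng, [1.0, 1.5], 400)
    model = tracking.fit_tracking_classifier(pos, neg)

    def _at(mu_t, day):
        # invert standardization and transform: scores at the class mean
        names = model.feature_pair
        raw = {}
        for k, (nm, v) in enumerate(zip(names, mu_t)):
            u = float(v * model.scale_sd[k] + model.scale_mean[k])
            raw[nm] = max(float(np.expm1(u)), 0.0) \
                if nm in ("isih_div", "acorr_div") else u
        raw.setdefault("max_r_z", 3.0)
        raw.setdefault("d_pamp", 0.1)
        raw.setdefault("isih_div", 0.2)
        raw.setdefault("acorr_div", 0.3)
        return tracking.SimilarityScores(day=day, **raw)

    days_pos = [_at(model.pos_mean, d) for d in range(1, 8)]
    dec = tracking.classify_unit_track(model, days_pos)
    assert dec.stable

    days_mixed = list(days_pos)
    days_mixed[3] = _at(model.neg_mean, 4)
    dec2 = tracking.classify_unit_track(model, days_mixed)
    assert not dec2.stable
    assert dec2.failure_day == 4
    # cumulative FP grows with horizon under independence
    assert np.all(np.diff(dec2.cumulative_fp) > 0)


def test_error_rate_estimation(rng):
    pos = _scores(rng, [4.0, 0.1], 200)
    neg = _scores(rng, [0.5, 2.5], 200)
    model = tracking.fit_tracking_classifier(pos, neg, target_error=0.05)
    labelled = [(s, True) for s in _scores(rng, [4.0, 0.1], 100)] + \
               [(s, False) for s in _scores(rng, [0.5, 2.5], 100)]
    fp, fn, fp_ci, fn_ci = tracking.estimate_error_rates(model, labelled)
    assert fp <= 0.1
    assert fn <= 0.2
    with pytest.raises(InsufficientDataError):
        tracking.estimate_error_rates(model, [])


def test_waveform_noise_monotonically_degrades_max_r(day0_session):
    """Mean Fisher-z of the waveform correlation falls as noise grows."""
    cfg_base = dict(trials_per_session=12, rng_seed=7,
                    neuron_counts={"type1_pn": 2, "type2_pn": 4,
                                   "type3_pn": 3, "interneuron": 2})
    zs = []
    for noise in (0.02, 0.2, 0.8):
        cfg = rl.SimConfig(**cfg_base, waveform_noise_sd=noise)
        wfs = synth.generate_waveform_series(cfg, day0_session["trains"])
        reps = []
        for i in range(len(wfs)):
            half = wfs[i].n_events // 2
            if half < 50:
                continue
            a = WaveformSet(wfs[i].unit_id, 0, wfs[i].events[:half])
            b = WaveformSet(wfs[i].unit_id, 0, wfs[i].events[half:])
            r, _ = tracking._max_shifted_correlation(
                a.mean_waveform(), b.mean_waveform())
            reps.append(np.arctanh(min(r, 1 - 1e-12)))
        zs.append(np.mean(reps))
    assert zs[0] > zs[1] > zs[2]


def _generator_score_clouds(cfg, pos_days=(2, 5), unstable_ids=None,
                            morph_fraction=0.5):
    """Cross-day same-unit positives and distinct-unit negatives."""
    kin, _ = synth.generate_session_kinematics(cfg, 0, 0)
    trains0, _ = synth.generate_ensemble_spikes(cfg, kin, 0)
    wfs0 = synth.generate_waveform_series(cfg, trains0)
    pos, neg = [], []
    by_day = {}
    for d in pos_days:
        kin_d, _ = synth.generate_session_kinematics(cfg, d, 0)
        trains_d, _ = synth.generate_ensemble_spikes(cfg, kin_d, d)
        wfs_d = synth.generate_waveform_series(cfg, trains_d,
                                               unstable_ids=unstable_ids,
                                               morph_fraction=morph_fraction)
        by_day[d] = (trains_d, wfs_d)
        for i in range(len(trains0)):
            try:
                pos.append(tracking.compute_similarity_scores(
                    (wfs0[i], trains0[i]), (wfs_d[i], trains_d[i])))
            except InsufficientDataError:
                pass
    for i in range(len(trains0)):
        for j in range(len(trains0)):
            if i != j:
                try:
                    neg.append(tracking.compute_similarity_scores(
                        (wfs0[i], trains0[i]), (wfs0[j], trains0[j])))
                except InsufficientDataError:
                    pass
    return (trains0, wfs0), by_day, pos, neg


def test_morphed_unit_lands_in_distinct_region():
    """A unit whose template morphs 50% per day scores like a distinct
    neuron under the model fitted on default stable/distinct clouds."""
    cfg = rl.SimConfig(trials_per_session=30, rng_seed=7,
                       neuron_counts={"type1_pn": 3, "type2_pn": 6,
                                      "type3_pn": 5, "interneuron": 3})
    (trains0, wfs0), _, pos, neg = _generator_score_clouds(cfg)
    model = tracking.fit_tracking_classifier(pos, neg)
    uid = trains0[0].unit_id
    kin5, _ = synth.generate_session_kinematics(cfg, 5, 0)
    trains5, _ = synth.generate_ensemble_spikes(cfg, kin5, 5)
    wfs5 = synth.generate_waveform_series(cfg, trains5, unstable_ids={uid},
                                          morph_fraction=0.5)
    s = tracking.compute_similarity_scores((wfs0[0], trains0[0]),
                                           (wfs5[0], trains5[0]))
    assert not model.predict_same([s])[0]


def test_stable_and_morphing_units_classified_with_high_accuracy():
    """Ground-truth confusion matrix on stable vs morphing units."""
    cfg = rl.SimConfig(trials_per_session=30, rng_seed=19,
                       neuron_counts={"type1_pn": 4, "type2_pn": 8,
                                      "type3_pn": 6, "interneuron": 4})
    (trains0, wfs0), by_day, pos, neg = _generator_score_clouds(cfg)
    model = tracking.fit_tracking_classifier(pos, neg)
    morph_ids = {t.unit_id for t in trains0[::2]}
    kin6, _ = synth.generate_session_kinematics(cfg, 6, 0)
    trains6, _ = synth.generate_ensemble_spikes(cfg, kin6, 6)
    wfs_stable = synth.generate_waveform_series(cfg, trains6)
    wfs_morph = synth.generate_waveform_series(cfg, trains6,
                                               unstable_ids=morph_ids,
                                               morph_fraction=0.5)
    calls_stable, calls_morph = [], []
    for i, tr in enumerate(trains0):
        s_stable = tracking.compute_similarity_scores(
            (wfs0[i], tr), (wfs_stable[i], trains6[i]))
        calls_stable.append(bool(model.predict_same([s_stable])[0]))
        if tr.unit_id in morph_ids:
            s_m = tracking.compute_similarity_scores(
                (wfs0[i], tr), (wfs_morph[i], trains6[i]))
            calls_morph.append(bool(model.predict_same([s_m])[0]))
    sensitivity = np.mean(calls_stable)
    specificity = 1.0 - np.mean(calls_morph)
    assert sensitivity > 0.9
    assert specificity > 0.9


def test_default_synthetic_scores_select_max_r_isih_pair():
    """On generator-default score clouds (cross-day same-unit positives,
    distinct-unit negatives) the information criteria choose
    (max_r_z, isih_div), the waveform-shape x firing-statistics pair."""
    cfg = rl.SimConfig(trials_per_session=30, rng_seed=7,
                       neuron_counts={"type1_pn": 3, "type2_pn": 6,
                                      "type3_pn": 5, "interneuron": 3})
    kin, _ = synth.generate_session_kinematics(cfg, 0, 0)
    trains0, _ = synth.generate_ensemble_spikes(cfg, kin, 0)
    wfs0 = synth.generate_waveform_series(cfg, trains0)
    pos, neg = [], []
    for d in (2, 5):
        kin_d, _ = synth.generate_session_kinematics(cfg, d, 0)
        trains_d, _ = synth.generate_ensemble_spikes(cfg, kin_d, d)
        wfs_d = synth.generate_waveform_series(cfg, trains_d)
        for i in range(len(trains0)):
            try:
                pos.append(tracking.compute_similarity_scores(
                    (wfs0[i], trains0[i]), (wfs_d[i], trains_d[i])))
            except InsufficientDataError:
                pass
    for i in range(len(trains0)):
        for j in range(len(trains0)):
            if i != j:
                try:
                    neg.append(tracking.compute_similarity_scores(
                        (wfs0[i], trains0[i]), (wfs0[j], trains0[j])))
                except InsufficientDataError:
                    pass
    model = tracking.fit_tracking_classifier(pos, neg)
    assert model.feature_pair == ("max_r_z", "isih_div")
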