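# reachlearn

Analysis toolkit for chronic extracellular recordings from motor cortex
during skilled forelimb-reaching learning.  It targets the question of
how the deep output layer (L5b) of rat M1 refines its movement
representation over a week of single-pellet reach training, and
implements the full chain such a study needs:

* **Unit quality** — isolation distance, L-ratio, SNR, refractory
  criterion (99.5% of ISIs > 2 ms), and multi-cluster separation
  statistics (MANOVA F, J3, Davies–Bouldin, Dunn) from per-event
  waveform features.
* **Cross-day unit tracking** — four similarity scores (maximum
  time-shifted waveform correlation, amplitude change, ISI-histogram
  and autocorrelogram divergences) combined by a quadratic classifier
  calibrated to a 5% error rate on known distinct-neuron pairs, plus a
  conservative mean + 3 s.d. rule.
* **Behaviour** — success rates, first-attempt delays, reach-phase
  durations, and dynamic-time-warping (DTW) deviation of each reach
  from an expert reference trajectory.
* **Movement information** — time-lagged mutual information
  `I(τ)` between binned spike counts and forelimb speed on the lag grid
  −500..+500 ms (12.5 ms steps), with `I_M = max_τ I(τ)` and
  `τ_opt = argmax`, a bootstrap null for significance, a DTW-warp
  control, PETH/time-until-divergence, PN/IN separation, functional
  typing of units by their 7-day `I_M` trajectories, and the
  mean-matched Fano factor.
* **Decoding** — ν-SVR (RBF kernel) prediction of instantaneous
  velocity from preceding population activity, with per-neuron window
  selection and cross-day transfer.
* **Population structure** — pairwise rate-correlation matrices and
  their cross-day similarity, and Gaussian-process factor analysis
  (GPFA) for single-trial latent trajectories with across-trial
  variance diagnostics.
* **Evoked potentials** — input–output curves, learning-related LTP as
  percent of baseline, and 1D current-source-density inversion
  (second-difference and spline-inverse).

No public recordings exist for this kind of study, so the package
includes a first-class synthetic-data generator (`reachlearn.synth`)
that emulates the experiment — 7 days × 6 sessions of reaching with a
learning curve, three functional neuron classes plus interneurons,
drifting waveforms, and sink-driven laminar field potentials — with
full ground truth, which the test suite uses for parameter-recovery
validation.  See `docs/methods.md` for the model and every numerical
choice.

## Worked example

```python
import numpy as np
import reachlearn as rl
from reachlearn import behavior, encoding, synth

cfg = rl.SimConfig(trials_per_session=115, rng_seed=0)   # defaults: 7 days x 6 sessions
kin, trials = synth.generate_session_kinematics(cfg, day=6, session=5)
spikes, truth = synth.generate_ensemble_spikes(cfg, kin, day=6, session=5)

speed = behavior.compute_velocity(kin)
unit = spikes[0]                                          # a type-1 (stable) unit
prof = encoding.mi_significance(unit, speed, vel_times=kin.timestamps,
                                n_boot=2000, seed=0)
print(f"I_M = {prof.i_m:.4f} bits at tau_opt = {prof.tau_opt_ms:.1f} ms "
      f"(threshold {prof.threshold:.4f}, significant={prof.significant})")

summary = behavior.summarize_behavior(trials)
print(summary.table[["success_rate_pct", "delay_mean_s"]].round(2).to_string(index=False))
```

Output:

```
I_M = 0.0034 bits at tau_opt = 150.0 ms (threshold 0.0005, significant=True)
 success_rate_pct  delay_mean_s
            46.09          0.96
```

The unit's firing carries significant information about forelimb speed,
maximal when firing precedes movement by 150 ms — exactly the lag the
generator planted — and the day-7 session shows the trained behaviour
(high first-reach success rate, short food-to-reach delay).

A configurable end-to-end pipeline with CSV/JSON outputs is available
as a CLI:

```bash
reachlearn --seed 1 --outdir out run-all      # or: python -m reachlearn ...
```

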