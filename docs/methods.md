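# Methods

`reachlearn` re-implements, as a tested library, the analysis chain used
to characterize how the deep output layer (L5b) of rat primary motor
cortex refines its representation of a skilled forelimb-reaching
movement over a week of training: chronic single-unit tracking,
movement-information statistics, functional cell typing, population
decoding, latent-trajectory variance, and evoked-potential plasticity.
Because no recordings are redistributable, the package ships a
synthetic-data generator that emulates the statistical structure of the
study's data with full ground truth; every analysis stage is validated
by parameter recovery against that ground truth and by independent
brute-force oracles.

## The simulated experiment

`synth.SimConfig` encodes the study conditions: 7 days x 6 sessions of
single-pellet reaching, 2D paw kinematics at 80 Hz (so one video frame
equals one 12.5 ms analysis bin), spike waveforms at 40 kHz, laminar
field potentials on a 20-channel probe with 100 um spacing at 1 kHz.

**Behaviour.** A per-session skill level `s` in [0, 1] follows a
saturating learning curve (most gain in the first three days, matching
the reported levelling-off of success rates).  Skill controls, linearly
unless noted: the first-success probability (8.7% -> 46.6%), the
food-to-orient delay (3.44 s -> 0.96 s, lognormal jitter shrinking with
skill), the six reach-phase durations (halved at full skill), and
smooth trajectory noise around a minimum-jerk out-and-back arc from the
slot to the pellet (noise floor 0.02 cm; 0.12 cm at zero skill).  Failed
reaches share the kinematic model but miss the pellet by a terminal
offset at grasp.  No reference coordinates exist for this task, so the
arc shape itself is a free choice; only its smoothness, duration
schedule and noise schedule matter downstream.

**Spiking.** Each unit is an inhomogeneous Poisson process
`lambda(t) = baseline + gain_day * g(v(t + lag_day))`, thinned from a
homogeneous envelope, with a 2 ms absolute refractory period enforced by
deleting any spike closer than 2 ms to the previously kept one (this
biases rates down by roughly `rate * 2 ms`, about 1% at 5 Hz, which the
rate-recovery tests account for).  The link `g` is speed rectified and
normalized by the session's 95th-percentile speed, clipped at 1.  We
use a robust percentile rather than the raw session maximum because the
maximum is an extreme-value statistic dominated by single-frame noise;
with max-normalization the effective coupling was too weak for lag
recovery at the 10-minute data lengths the analyses assume.  Class
defaults: type 1 (stable movement-coding) baseline 9.2 Hz, constant
gain 8 Hz and constant lag 150 ms; type 2 (task-recruited) baseline
5.9 Hz, gain rising 1 -> 8 Hz and lag shrinking 225 -> 141 ms across
days (an 84 ms reduction, the headline refinement scale); type 3 gain
0; interneurons higher baseline (15 Hz) with narrow waveforms.  The
day-1 type-2 gain of 1 Hz puts those units in the regime the study
describes: their lag is estimable from a full day of behaviour (noisy,
tens of ms) while their 5-minute I_M stays below the significance
threshold.  In the
dopamine-depleted scenario (`lesion_mode`) each morning retains only
`lesion_retention` (default 25%) of the previous evening's skill, and
the learned type-2 gain/lag schedules are compressed toward their day-1
values by the same factor — producing the overnight de-learning and
LTP sawtooth the lesion experiments show.

**Waveforms.** Two-Gaussian biphasic templates, 32 samples at 40 kHz,
with class-dependent width/ratio and broad across-unit parameter
diversity (distinct neurons correlate well below stable re-recordings
of the same neuron).  Stability-relevant corruption has three knobs:
per-event white noise and lognormal amplitude jitter; a slow template
shape drift (2% of amplitude, resampled smoothly each day); and a
per-session lognormal amplitude random walk (sigma 0.02/session)
emulating electrode-to-soma distance fluctuation — this is what makes
peak-to-peak amplitude a weaker tracking feature than waveform shape,
as in real chronic recordings.  An `unstable` flag morphs a template
toward a different one to emulate lost/exchanged units.

**Field potentials.** A balanced depth profile (Gaussian sink at the
deep-layer depth flanked by two sources scaled so the depth integral is
exactly zero) with an alpha-function time course drives the 1D Poisson
relation `sigma d2(phi)/dz2 = -C`, solved discretely with grounded
virtual channels beyond the probe.  Because generation uses the planar
(infinite-slab) relation, the forward-inverse consistency check runs
the spline-inverse estimator with a wide source disc (2 mm); the
default 500 um disc is the realistic-geometry setting.

What the generator does **not** emulate: overlapping spikes and sorting
failures, non-Poisson firing statistics (bursting, adaptation),
electrode drift within a session, EMG or licking artefacts, and any
causal link between neural activity and behaviour (kinematics drive
spikes, never the reverse).  Passing tests therefore demonstrate that
the analysis chain recovers planted structure of the assumed form at
realistic SNR and data lengths — not that it is robust to every failure
mode of real recordings.

## Analysis stages and key numerical choices

**Sorting quality** (`quality`): energy/peak/valley plus three PC
scores (six features, single-channel convention); isolation distance as
the squared Mahalanobis radius (cluster covariance) of the n-th closest
noise event; L-ratio as the chi-square upper-tail mass (df = feature
count) of noise events, over cluster size; SNR as peak-to-peak of the
mean waveform over the noise amplitude, with the noise amplitude
defaulting to 2x the RMS residual around the mean when no independent
estimate exists (no standard formula exists for this estimator).  MANOVA F uses
Wilks' lambda with Rao's approximation on the first two PCs; J3 is the
between/within scatter ratio divided by the cluster count;
Davies-Bouldin is negated so that larger is better everywhere.
Undefined metrics are NaN, never zero; singular covariances get
diagonal loading and a flag.

**Cross-day tracking** (`tracking`): four scores — Fisher-z of the
maximum time-shifted waveform correlation (shifts up to +/-5 samples;
the choice is free, and at 40 kHz this covers realistic
jitter), normalized peak-to-peak amplitude difference relative to the
reference day, and Jeffreys-symmetrized KL divergences (pseudocount
1e-10/bin) of log-binned ISI histograms (0.5-1e5 ms, 100 bins) and
autocorrelograms (+/-100 ms; 50 log-spaced magnitude bins mirrored to
negative lags, since log bins cannot straddle zero).  Divergences are
log1p-transformed, and all features standardized by pooled mean/s.d.
before the class-conditional Gaussian fit so that AIC/BIC model
selection across the six feature pairs ranks class structure rather
than raw scale; ties break toward pairs containing the waveform
correlation.  The quadratic boundary is shifted to put 5% of training
negatives on the positive side; a unit is stably tracked only if every
day both passes the calibrated QDA call and lies outside the 3 s.d.
Mahalanobis contour of the distinct-pair cloud.  On default generator
data the selected pair is (max r, ISIH divergence).

**Behaviour** (`behavior`): classical DTW (Euclidean local cost, steps
{(1,0),(0,1),(1,1)}, no global band by default); the expert
reference averages 50 random first-success trials from the final
session after linear time-normalization to the median length; matched
trials are those within mean +/- s.d. of the pool's DTW deviation,
sampled without replacement with a seeded RNG.

**Movement information** (`encoding`): spike counts on the 12.5 ms
grid paired with speed shifted by tau (positive tau = firing precedes
movement), lags -500..+500 ms (81 points).  Speed is reduced to 8
quantile bins — the discretization is an open choice; quantile
binning equalizes the marginal and makes the estimator exactly
invariant under strictly monotone velocity transforms.  Counts are
clipped at 7 (larger counts are vanishingly rare at these rates).  The
plug-in estimator's bias is not corrected: significance is judged
against a null with the same bias, built by resampling count bins with
replacement (destroying temporal pairing, preserving the marginal) and
recomputing the full-profile maximum per resample; the threshold is
the null's 99th percentile.  The default 2000 resamples give the 99th
percentile a relative accuracy of a few percent; a circular-shift null
is available as an alternative.  The resampling loop is a numba kernel
that only touches nonzero count bins, making the prescribed
500-neuron x 2000-resample calibration run in minutes.  PETHs use the
12.5 ms grid, a 5-point Gaussian kernel with sigma = 1 bin, and
baseline z-scoring; time-until-divergence needs 5 consecutive bins at
p < 0.01 against a bootstrap of baseline bins.  PN/IN separation is
k-means (k = 2, 20 seeded restarts) on z-scored width/ratio/rate;
functional typing is Ward linkage on the 7-day I_M vectors with the
cluster count chosen by Calinski-Harabasz over k in [2, 8], clusters
mapped to types by the majority significance pattern of their members
(significant day 1 and day 7 -> type 1; day 7 only -> type 2; else
type 3), and the type-2 lag change tested by paired t-test.
Significance for typing follows the emulated study design of bootstrapping a
5-minute recording segment, while per-day I_M and tau_opt pool all of a
day's sessions — weakly coupled units can then carry an estimable lag
while remaining non-significant, which is exactly the task-recruited
day-1 phenotype.  The
mean-matched Fano factor uses 50 ms windows in 10 ms steps, a common
mean-count histogram (20 grid cells) subsampled 50 times per bin, and
a variance-on-mean regression through the origin.

**Decoding** (`decoding`): nu-SVR (RBF kernel, nu = 0.5, the midpoint of the
admissible range (0, 1]) on per-neuron lagged count windows
normalized to [0, 1].  The admissible (cost, gamma) ranges are
log2 c in [-5, 10] and log2 g in [-10, 5]; the default searched grid is
a coarse interior subset ({-2, 2, 6} x {-6, -2, 2}) chosen for
convergence speed at desk scale, with the full ranges reachable by
argument.  Per-neuron window selection maximizes 5-fold CV r^2 over
windows up to 500 ms and declares a neuron non-informative when its
best score stays inside a circular-shift chance band (shift preserves
the target's autocorrelation; a Sidak adjustment accounts for
best-of-grid selection).  Same-day evaluation holds out the final 20%
time block to avoid temporal leakage; cross-day transfer evaluates each
day's model on the previous day.

**Population structure** (`population`): pairwise squared Pearson
correlations of 12.5 ms rates smoothed with sigma = 2 bins (25 ms; the
source states no width), concatenated over food-provided -> complete
windows; matrix similarity is the Pearson correlation of off-diagonal
elements, defined only for identical unit orderings.  The latent model
is GPFA: square-rooted 10 ms counts, linear-Gaussian observation with
diagonal noise, unit-variance squared-exponential GP priors per latent
(fixed 1e-3 jitter), fitted by EM exploiting the Kronecker structure of
the posterior precision.  Timescales initialize at 100 ms and are
updated by bounded scalar maximization of the expected complete-data
likelihood (a generalized-EM step), so the marginal log-likelihood —
computed every iteration via the matrix inversion lemma — must never
decrease; a decrease raises `ConvergenceError` with the iteration log.
Loadings are orthonormalized by SVD and dimensions ordered by the
empirical variance of the projected latents; the top 3 of 8 latents are
reported by default.  Across-trial variance diagnostics integrate the
per-time covariance diagonal over the -800..+800 ms window around
orient.

**Field potentials** (`fp`): amplitude = post-stimulus peak negativity
minus pre-stimulus baseline; initial slope fitted over the 20-80%
segment of the rise (a conventional reading of the initial slope).  The I/O curve
uses the 40-1000 uA intensity ladder, isotonic regression when
non-monotone, and interpolated 50% (configurable 25-75%) test-intensity
selection.  LTP is percent-of-baseline for slope and amplitude; the
lesion scenario's overnight de-potentiation is detected by a sign test
on day-boundary steps.  CSD: second-difference with Vaknin boundary
duplication (a conventional default), or
spline-inverse CSD — a forward matrix built from natural-cubic-spline
source profiles integrated against the disc-source electrostatic
kernel (sigma = 0.3 S/m, 500 um disc by default), inverted directly or
by pseudo-inverse when ill-conditioned (condition number recorded).

**Pipeline** (`pipeline`): JSON/TOML-configurable orchestration of all
stages on simulated data, one analysed session per day, every table
stamped with the configuration hash and seed; re-running a
configuration reproduces all numbers exactly.  The CLI (`reachlearn`)
exposes one subcommand per stage; results go to files, logs to stderr.

## Problem sizes

Tests and the acceptance script run everything at desk scale on one
CPU: sessions of 12-115 trials (60 s-10 min of data as each analysis
requires), ensembles of 11-40 units, 2000 bootstrap resamples, 300-500 resamples where only a rough
threshold is needed, GPFA with 3-5 latents on 15-30 trials x 160 bins,
and SVR on series of about 2000 bins with the coarse default grid.
The bootstrap calibration (500 neurons x 2000 resamples) and the
typing/decoding recoveries are the longest steps, a few minutes each.

## Known limitations

The plug-in MI bootstrap test is mildly anti-conservative at finite
data lengths (the conditional null slightly underestimates the
unconditional spread of the observed maximum); at the prescribed
5-minute lengths the empirical false-positive rate sits near the
nominal 1% but the discrepancy grows for shorter spans.  Mean-matched
Fano estimates are noisy when the common mean distribution is thin.
The spline-inverse CSD assumes the generator's planar geometry only in
the wide-disc limit.  DTW is quadratic in trial length and implemented
in Python loops; at 80 Hz reach durations this is fast enough, but
minute-long traces would need a compiled implementation.  Tracking
calibration assumes the training negative cloud represents future
negatives; the conservative 3 s.d. rule guards against positives drawn
from an optimistically tight same-day cloud.
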