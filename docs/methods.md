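# Methods

This note documents the models and procedures implemented in `stridesense`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data results do and do not show about real recordings.

## Data model

A raw recording is a 9-channel matrix X(t) = [a(t); ω(t); m(t)] — triaxial
acceleration, angular velocity and magnetic orientation — sampled at a fixed
rate (256 Hz default, matching public labelled running datasets). Condition
labels are binary: fatigued (`F` → 1, recorded after an exhaustive
incremental shuttle-run protocol) versus non-fatigued (`NF` → 0). Label
parsing is case-insensitive and whitespace-trimmed. Time is implicit (row
index over sampling rate); acceleration units are a stored metadata tag
("m/s2" or "mg") and never converted implicitly. Stride datasets store one
CSV row per (stride, channel) with fixed-length sample columns, which keeps
the files standard-parseable and diffs readable; recording metadata lives in
a JSON sidecar rather than CSV comments for the same reason. Both writers
emit 17 significant digits so write→read round-trips are lossless.

## Preprocessing

Order: low-pass filter → detrend → z-normalize → segment. Filtering is a
Butterworth low-pass applied forward–backward (`sosfiltfilt`), because
stride *shapes* feed a DTW comparison and must not be phase-shifted; the
effective magnitude response is the squared one-pass response. Default
cutoff 20 Hz, order 4 — gait energy in running sits below ~15 Hz, and the
zero-phase 4th-order roll-off suppresses a tone at 5× the cutoff to well
under 5% RMS. Padding is widened to 30× the filter order so edge transients
(and hence asymmetry on symmetric inputs) stay at machine precision.
Normalization comes last so per-stride statistics are comparable across
participants and sensors; a constant channel z-normalizes to zeros with a
logged warning rather than an error.

Segmentation detects peaks on the *filtered acceleration composite
magnitude* with a minimum inter-peak distance (default 0.4 s) and a
prominence floor (default 0.5 standard deviations of the filtered
magnitude); each inter-peak interval is one stride, linearly resampled to a
fixed L_stride = 128 samples per channel so downstream feature matrices and
sequence tensors are rectangular. Peak-to-peak segmentation is a standard
choice for lumbar-mounted running data, where gravity plus impact loading
give the magnitude one dominant peak per gait cycle; recordings that are
constant or contain fewer than two detectable peaks raise a segmentation
error carrying the peak count.

## Features

Per configured channel (default the acceleration triad):

* time-domain: mean, median, variance, RMS, min, max, IQR. `variance` is
  the population variance (ddof = 0) so the identity rms² = mean² +
  variance holds exactly — a useful internal consistency check.
* frequency-domain: one-sided periodogram of the mean-removed channel,
  scaled so the bins sum to the population variance (discrete Parseval).
  Derived: total power, dominant frequency, Shannon spectral entropy in
  bits (bounded by log₂ n_bins, scale-invariant), and band powers over
  [0, 3), [3, 10), [10, Nyquist] Hz — gait-scale edges, configurable.
* sample entropy with m = 2, r = 0.2·sd, Richman–Moorman template counting
  (n − m templates at both lengths, so a constant series scores exactly 0);
  when no (m+1)-template repeats the value is +∞, flagged and imputed at
  dataset level with the finite-sample column median.
* SMA of the acceleration triad.

This is the smallest concrete set covering the named families; the exact
list is a declared instantiation, not an attempt at optimal feature
selection. Extraction is deterministic given dataset and config.

## Fatigue classification

`FatigueClassifier` wraps 14 classical families (extra trees, random
forest, QDA, kNN, decision tree, gradient boosting, logistic regression,
AdaBoost, LDA, ridge, LightGBM, linear SVM, Gaussian naive Bayes, and an
all-positive dummy baseline) behind one fit/score/threshold surface.
Scores are class-1 probabilities where the family provides them, otherwise
a sigmoid-squashed decision function; the thresholding rule is
predicted = 1{score ≥ τ}, boundary inclusive, τ default 0.5. The positive
class is *fatigued* throughout, so recall reads as "fraction of fatigued
strides detected". Scale-sensitive families (kNN, logistic, ridge, SVM) are
standardized inside the estimator; QDA is preceded by a PCA that drops the
exactly-null directions created by linearly dependent features (band powers
sum to total power) and regularized with reg_param 0.1.

Metrics come from the confusion matrix with a zero-division convention of
0-with-warning so benchmark tables stay total. For the all-positive
baseline, precision = accuracy = positive prevalence and recall = 1 on any
dataset with positives — the identity the benchmark harness verifies.

Cross-validation defaults to subject-wise grouping (all strides of a
participant in one fold) to prevent identity leakage; a stratified
per-stride alternative is provided, since published benchmark tables on
this task do not always state their protocol and the two regimes can differ
substantially. Exact reproduction of any externally published benchmark
numbers is out of scope: they depend on the external dataset and an
unstated validation protocol.

The LSTM sequence model (single LSTM layer, 2-unit softmax dense head;
reference configuration epochs 5000, batch 32, validation split 0.1) is
implemented over raw stride tensors behind an optional PyTorch backend;
without a backend it raises a capability error, and no other path depends
on it. Desk-scale tests use heavily reduced epochs.

## Stamina metric

Z is deliberately the simplest monotone map satisfying "normalized distance
to the athlete's own non-fatigued baseline":

* template: pointwise median of the participant's NF strides (median, not
  mean, for robustness to the occasional outlier stride);
* scoring series: z-normalized acceleration composite magnitude
  (configurable to any single channel);
* scale: κ = 95th percentile of the NF strides' own DTW distances to the
  template, floored at 10⁻⁶·L_stride to guard division by zero for
  perfectly repeatable synthetic athletes;
* Z = clip(1 − d/κ, 0, 1), categorized low/medium/high at (1/3, 2/3), with
  intervals closed below and open above except the top band.

Because κ is calibrated from the NF distance distribution itself, a typical
NF stride scores a small positive Z (its distance is close to the 95th
percentile when the distances concentrate, as they do when measurement
noise dominates the shape differences), and strides whose distance exceeds
the worst calibration stride score 0. Z therefore reads as a *relative*
closeness-to-baseline index, not an absolute physiological quantity; what
is asserted and tested is ordinal: fatigued strides score systematically
below non-fatigued ones when a real amplitude effect exists, and the gap
vanishes under the null. A regression of a model onto Z would collapse onto
the defining formula (Z has no independent operationalization), so the
direct formula is the implementation; ground-truth stamina for validation
exists only in the synthetic setting, where the generator's amplitude
factor supplies it.

DTW semantics are pinned so external implementations can be configured to
match: local cost |aᵢ − bⱼ|, steps {(1,0), (0,1), (1,1)} with unit weights,
boundary-anchored monotone paths, no path-length normalization of the
stored distance (normalization enters only through κ), optional Sakoe–Chiba
band on |i − j|. Ties in the backtrack prefer the diagonal. The dynamic
program is checked against exhaustive path enumeration in the test suite.

## Bias estimation, localization, minimization

B = mean(ŷ − y) over a validation set; correction subtracts B, making the
corrected series unbiased against the same truths to round-off (an
algebraic identity, verified to 1e-12). Localization scores each feature by
|Pearson r(feature, residual)|, ranked descending with name-ordered
tie-breaks; constant columns score 0 with a warning. The minimization loop
alternates estimate → localize → fit a linear residual model with intercept
on the top-k (default 3) localized features → subtract, until |B| ≤ ε.
The intercept absorbs a pure constant offset in one iteration; a bias
linear in one feature is recovered with that feature ranked first. The
linear residual correction is the minimal member of the
gradient-descent/feature-transformation family of correction functions and
the only one whose convergence can be asserted analytically; hitting the
iteration cap reports converged = False rather than raising, so batch runs
stay total.

## Training-load control

The controller is a bounded proportional law — the degenerate-horizon
member of the model-predictive-control family:

    i′ = clamp(i − α·k_f·(I_fatigue − setpoint) + α·k_s·(I_stamina − 0.5))

with duration updated analogously through a per-parameter gain scale
(minutes per unit error, default 0 = duration held fixed). The stamina
observation enters relative to a fixed 0.5 reference since no natural
stamina setpoint exists. The simulated athlete is a stable first-order
plant: Fat′ = ρ·Fat + β·i·d + process noise, Sta′ = clamp(1 − Fat′/scale),
observations = latents + optional systematic offset + noise. Defaults
ρ = 0.6, β = 0.02 per intensity-minute put the open-loop fixed point
β·i·d/(1 − ρ) near mid-scale for a 45-minute session at intensity 0.5.

For fixed duration and k_s = 0 the closed loop is a coupled linear
recurrence with fixed point exactly at the setpoint (implied intensity
i* = setpoint·(1 − ρ)/(β·d)); it contracts when α·k_f·β·d < 2(1 − ρ),
and the convergence tests run inside that region with duration fixed so the
1-D analysis applies. Observed indicators are bias-corrected with a rolling
window (default 10 sessions) against the plant's latent truths — the one
setting where truths exist — before entering the control law; this removes
a systematic observation offset exactly once the window fills. Bounds are
enforced by clamping and hold on every trajectory, noisy or not.

## Synthetic cohorts

The generator emulates the reported fatigue signatures, not biomechanics:
each stride channel is a two-harmonic gait template (fundamental plus
half-amplitude 2nd harmonic, per-axis phase offsets), scaled by a
per-participant amplitude A_p = base·(1 + participant_sd·z_p), attenuated
multiplicatively by (1 − δ) under fatigue; Gaussian noise with
σ_NF = 0.1·base inflated by (1 + γ) under fatigue; and, with probability
`outlier_prob` per fatigued stride, a single spike of `outlier_scale`·A_p
on a random acceleration axis. δ = γ = outlier_prob = 0 defines the null
configuration, in which the condition labels are exchangeable. The
continuous-recording generator adds the gravity offset on the vertical axis
so the composite magnitude is single-peaked per gait cycle, as in real
lumbar data. Defaults (δ = 0.3, γ = 0.5, 5% outliers, 5% participant
spread) make the effect clearly learnable without being trivial; no
quantitative effect sizes are published for these shifts, so they are free
parameters of the study design, chosen once.

What passing tests show: the pipeline detects multiplicative
amplitude/variance effects of the stated size, at the stated sample sizes,
under ideal segmentation. What they do not show: performance on real
running data, where stride variability is autocorrelated, fatigue onset is
gradual rather than binary, sensors drift, and the effect size is unknown —
on the public labelled dataset, published benchmarks hover near chance,
which is consistent with a much smaller real effect than the synthetic
default.

## Problem sizes and numerical choices

Simulation-backed checks use cohorts of 30–200 strides, 10–20 seeds per
claim with median aggregation, 500-session control trajectories, and
exhaustive DTW verification over all sequence pairs of length ≤ 4 on a
3-symbol alphabet — sizes at which every claim is decided in seconds to a
couple of minutes on one CPU. Fixed tolerances: 1e-12 for algebraic
identities, 1e-9 for normalization/detrend contracts, 1e-6 relative for
the Parseval identity, 1e-8 for filter symmetry. Degenerate inputs
(constant series, single-class labels, too few NF strides, infeasible DTW
bands) raise typed errors or warn-and-continue exactly as documented per
operation.

## Known limitations

* Stride segmentation assumes a dominant peak per gait cycle in the
  acceleration magnitude; heavily pathological gait or loose sensor
  mounting can violate this.
* Z is relative to a per-athlete calibration window; it is not comparable
  across athletes without identical calibration protocols.
* The bias loop corrects biases expressible as linear functions of the
  monitored features; non-linear systematic error reduces but need not
  reach ε.
* The athlete plant is first-order and linear; it is a test harness for
  the controller, not a physiological model — controller gains tuned on it
  should be re-tuned on real response data.
* The LSTM path requires an optional backend and is excluded from all
  critical guarantees.
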