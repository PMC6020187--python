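# Methods

This note documents the models, the numerical choices, and what the bundled
synthetic generator does and does not emulate. Everything stated here is
computed by the test suite or `scripts/acceptance.py`; nothing is quoted
from external data.

## Signal model and pre-processing

A trial couples 12 surface-EMG channels (7 upper-arm, 5 forearm muscles)
sampled at 1000 Hz with one elbow-goniometer angle trace. The linear
envelope is `lowpass(|emg|)` with a 7th-order Butterworth at 20 Hz
(second-order sections for numerical stability at order 7). Filtering is
**causal** by default: the decoder is meant to drive an online controller,
so we accept the filter's group delay rather than use information from the
future; `zero_phase=True` (forward–backward) is available for offline
analysis. The acquisition band-pass (30–350 Hz) is treated as applied in
hardware; `bandpass_raw` exists for fully synthetic raw signals.

Per-channel normalization divides by the channel's maximum over a
**reference set of trials**. The evaluation pipeline uses the training
trials as reference (no test-set leakage); `normalization="all"` reproduces
normalization over the whole session. A zero reference maximum is an error
naming the channel.

Angular velocity is a centered finite difference of the angle after a
50 ms moving average (reflect-padded); the smoothing stabilizes the
10 %-of-max threshold crossings against sample noise. Acceleration is the
derivative of velocity.

## Phase segmentation

With `v_thr = 0.1 · v_max` (the subject's maximum angular velocity over the
training trials; per-trial maximum as fallback):

* onset — first sample with `v ≥ v_thr`;
* peak — argmax of velocity from onset on;
* reach end — first sample after the peak with `v ≤ v_thr`;
* phase-3 end — reach end + `round(0.25 · (reach_end − onset))`, truncated
  (and flagged) at the end of the recording.

The crossing samples are included in the reach; inclusive crossings and
strict ones differ by at most one sample. Phase intervals are half-open on
the left edge of the next phase, so the peak sample belongs to phase 2 and
the reach-end sample to phase 3. A velocity that never exceeds the
threshold raises "no motion detected"; one that never re-crosses it flags
the trial as an incomplete reach. Windows are assigned the phase of their
final sample — the causal convention an online controller must use.

## Features and decoders

Sliding windows of 150 ms with 50 ms increments. Features per channel:
mean activation, waveform length, and slope-sign changes with a deadband
`eps = 0.01` (1 % of the normalized range; `eps = 0` recovers the raw
count). Feature vectors are ordered `[MA × N, WL × N, SSC × N]`.

* **LDA** — class means, pooled covariance with Ledoit–Wolf scalar
  shrinkage toward the identity (36-dimensional features from 20 trials per
  class are otherwise ill-conditioned; `shrinkage=None` raises on a
  singular covariance). Posteriors are exact Gaussian posteriors under the
  shrunk covariance; they match a brute-force density-ratio oracle to
  1e-8 and sklearn's LDA when shrinkage is off.
* **SVMs** — scikit-learn `SVC` behind a `StandardScaler`, one-vs-one
  multiclass. `C` (and `γ` for RBF) are selected by mean 4-fold
  cross-validated window accuracy; folds are stratified **by trial** so
  overlapping windows of one trial never straddle a fold boundary. Ties go
  to the smallest hyper-parameter (grids scanned in ascending order with
  strict improvement).
* **ESN** — reservoir `x(t) = tanh(W_in u(t) + W x(t−1))`, `x(0)=0`, driven
  by the raw normalized envelopes (no feature extraction). `W` is sparse
  uniform random (connectivity 0.1) rescaled to an exact spectral radius;
  `W_in` dense uniform with input scaling 1. The readout is a ridge
  regression from states (plus bias) to one-hot class targets; the first
  100 ms of states per trial are discarded as washout. A window's score is
  the mean readout output over its samples, which aligns the ESN with the
  50 ms decision cadence of the feature classifiers. Reservoir size, ρ and
  the ridge λ are grid-searched with the same trial-stratified CV; states
  are computed once per reservoir and reused across folds and λ values.
  Equal-length trials are advanced through the reservoir in lock-step
  (batched matrix products), which is what makes the grid search tractable.

Default protocol: 10 test and 20 train/validation trials per class,
stratified, reproducible under a seed. Default grids span the usual orders
of magnitude (`C ∈ 10^{-2..2}`, `γ ∈ 10^{-3..1}`, 100–500 neurons,
ρ ∈ {0.5, 0.8, 0.9, 0.99}, λ ∈ 10^{-6..0}); the experiments in the test
suite and the acceptance script use reduced grids (`C ∈ {1, 10}`,
`γ ∈ {10^{-3}, 10^{-2}}`, one 100-neuron ρ=0.9 reservoir, λ ∈ {10^{-4},
10^{-2}}) — selections on the synthetic data sit inside these ranges and
the reduction keeps a full four-classifier comparison within minutes on one
CPU.

## Majority-vote decision layer

Per-window votes enter a buffer covering the last 0.5 s (10 votes at the
50 ms cadence). The winner is the modal class; ties break to the most
recent vote among the tied classes. Confidence is the modal count divided
by either the votes received so far (`occupancy`, the library default) or
the fixed capacity (`capacity`). The trigger fires at the first step with
confidence **strictly** above the threshold (default 0.5) and is immutable.

The online replay (`run_online_simulation`) uses the **capacity**
denominator: under the occupancy rule the very first vote has confidence
1.0 and every trial would trigger ~50 ms after onset, making latency
meaningless; with the capacity rule a trigger needs six agreeing votes
within the last ten, so the minimal latency is ≈ 0.3 s — the regime in
which "time to confidence" measures decision quality. Voting starts with
the first window that ends at or after the detected motion onset (the
controller is armed by the goniometer); latency is measured from onset.
Trials that never trigger are counted separately and score as incorrect.

## Phase-structure statistics

Per trial and phase, the per-channel mean envelope forms an N-vector
(N = 12 or 5). The one-way MANOVA across the three phases computes the
within/between scatter matrices E and H, Wilks'
`Λ = det(E)/det(E + H)` with Rao's F approximation (exact here since the
factor has 2 degrees of freedom) and the Pillai–Bartlett trace
`V = tr(H(H+E)^{-1})` with its standard F approximation. Identical groups
give Λ = 1 and V = 0 exactly; in one dimension the Wilks F equals the
ANOVA F; under the null the 5 % rejection rate is calibrated by Monte
Carlo to [0.035, 0.065]. The implementation is cross-checked against
statsmodels' MANOVA in the tests.

For the geometric picture, sliding-window mean-activation vectors are
computed **within** each phase interval (the signal is cut at the phase
boundaries first, so no window mixes phases), a 2-component PCA is fitted
on the phase-3 vectors only (phase-3 centering puts that cloud at the
origin), phases 1–2 are projected into the same plane, and each phase's
2-D cloud is fitted with a full-covariance Gaussian mixture whose component
count `k ∈ 1..5` minimizes BIC (10 EM restarts, covariance floor 1e-6).
Pairwise phase overlap is the Monte-Carlo Bhattacharyya coefficient
`∫√(p q)`, estimated symmetrically from samples of both mixtures.

## The synthetic generator

The generator produces the study conditions, not arbitrary data. Defaults:
five grasp types × 30 trials, 4 s trials at 1000 Hz, reach duration
N(1.4 s, 0.25 s) for the amputee profile (N(1.1, 0.15) able-bodied), elbow
extension 90°→180° along a beta-shaped velocity bell whose peak is placed
(by a small fixed-point correction) at a uniform 30–45 % of the
above-threshold reach interval.

Activation profiles ride on a tonic level (postural tone / phantom-limb
effort; muscles are not silent during a reach) and differ by subject kind:
amputee forearm ramps gradually through the reach and then rises to the
grasp squeeze during the post-reach hold; amputee upper arm tracks
velocity up to the peak and holds constant; able-bodied forearm is a bump
peaking at ~40 % of the reach that decays toward completion, upper arm
tracks the velocity bell.

Grasp classes modulate per-muscle amplitudes. Each class has **one
signature vector per phase** (unit-RMS over the 12 channels): the phase-2
signature correlates 0.5 with phase 3 and phase 1 correlates 0.2 with
phase 2, with innovations drawn orthogonal to the span of all phase-3
signatures so the cross-phase geometry is exact rather than fluctuating
between datasets. This is the generative form of the finding the method
rests on — the muscle pattern of a grasp *morphs* across the motion phases
rather than merely growing. The expressed modulation is
`1 + class_separation · 0.5 · Σ_p s_p w_p(t) δ_{k,p}`, with the per-phase
strengths `s = (0.35, 0.75, 1.0)` (zero before onset, 100 ms smoothed
transitions). `class_separation = 0` therefore yields label-independent
signals (the chance-level control), and a fully deterministic
configuration (no noise, fixed duration) yields perfectly separable
classes.

Variability, all multiplicative log-normal unless stated: 15 Hz
band-limited envelope noise (sd 0.35 of the local amplitude — the
fluctuation level of a rectified-and-smoothed stochastic carrier),
per-trial overall effort (sd 0.25), per-trial proximal/distal balance
(sd 0.25 per group), per-trial per-channel gain (sd 0.10), a slow ~1.5 Hz
within-trial effort wander (sd 0.20), per-dataset per-channel amplitude
templates (jitter sd 0.15), plus small additive noise (sd 0.01). The
trial-level effort and balance axes are what force a classifier to encode
grasp identity in pattern *shape* rather than absolute amplitude — the
property that makes a phase-3-trained decoder genuinely ambiguous (rather
than merely biased) when extrapolating to early-reach data, as the
deployed comparison requires. `class_modulation_scale = 0.5` is calibrated
so a 3-class problem is solvable at ≥ 80 % accuracy from phase 2 on.

An optional raw-EMG mode emits 30–350 Hz Gaussian carrier noise amplitude-
modulated by the envelope (scaled by √(π/2) so the rectified mean recovers
it), to exercise the full pre-processing path.

What the generator does **not** emulate: motor-unit physiology, electrode
shift, motion artifacts and power-line interference, fatigue and
session-to-session drift, inter-subject variability (one synthetic subject
per dataset), hand-aperture kinematics, and TMR-specific reinnervation
effects (subject-group labels are metadata only). Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes, not that
it would reach any particular accuracy on recorded human EMG.

## Experiment orchestration

Offline evaluation trains one decoder per configuration and scores the
**majority-vote output** at each 50 ms step of each test trial (the
occupancy rule, votes starting at motion onset): per-phase confusion
matrices (rows = ground truth), per-phase accuracies, and an
accuracy-evolution curve over the 2 s after onset, per-trial curves aligned
at onset and padded at both ends with the nearest decision state, reported
as mean ± standard error over test trials.

The muscle-set comparison reruns the identical split with all 12 channels
vs the 5 forearm channels and pairs the per-trial, per-phase accuracies in
a paired t-test. The online comparison trains on all phases vs phase-3
windows only (for the ESN, envelope segments cut to phase 3), streams each
test trial through the decision layer, and compares trial-level
correctness and the trigger latencies of correct trials with two-sample
t-tests. The online default is the full five-grasp task. Group comparisons
use a two-sample t-test (two groups) or one-way ANOVA (more), with an
exact-equality fast path when every group is constant.

## Problem sizes and known limitations

The shipped experiments use the default 150-trial dataset (criteria on
phase profiles, chance level, muscle sets), a 225-trial dataset with
20 test trials per class for the online comparison, 1000 Monte-Carlo
replicates for the MANOVA calibration, and 20 seeds for the BIC-recovery
check — sizes chosen so the whole suite runs in minutes on a single CPU
while every comparison retains clear statistical power.

Limitations worth knowing:

* The chance-level check uses per-trial majority outcomes (windows within
  a trial are strongly correlated, so trials are the valid binomial unit)
  with a Bonferroni-simultaneous interval across the 12 classifier × phase
  cells.
* At the default (strong) class separation, the class modulation dominates
  the phase-3 PCA variance and the per-phase GMMs of phases 2 and 3
  overlap substantially; the qualitative pattern in which the post-reach
  phase separates from both reaching phases while phases 1–2 overlap each
  other emerges in the weak-separation regime
  (`class_separation ≈ 0.3` with quieter trial-level gains), which is
  where the property test for it operates. Weak separation is also the
  regime the recorded-data accuracies (~60 % for five grasps) correspond
  to.
* The two-class online task (the deployed hardware supported two grasps)
  is statistically fragile for the latency comparison: a phase-3-trained
  decoder's extrapolation bias favors one class per dataset and hands that
  class floor-latency triggers. The five-class default dilutes this
  artifact; with two classes the latency direction still holds on most,
  but not all, dataset seeds.
* Causal envelope filtering delays all envelopes by the filter's group
  delay (~20 ms at 20 Hz); latencies include it, consistently across
  conditions.
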