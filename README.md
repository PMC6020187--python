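# reachgrasp

Decoding the intended grasp type from surface EMG **while the arm is still
reaching**, so that a myoelectric prosthesis can begin closing in synergy
with the arm instead of one second after it stops.

Conventional pattern-recognition control trains a classifier on static
muscle contractions; during a dynamic reach-to-grasp motion the EMG
patterns drift and such a classifier generalizes poorly. This package
implements the alternative: segment each reach into three phases from the
elbow angular velocity, train decoders on windows from the *whole* motion,
and time the grasp command with a majority-vote confidence rule.

The pipeline, end to end:

1. **Pre-processing** — full-wave rectification and a 7th-order Butterworth
   low-pass at 20 Hz produce linear envelopes from 12 EMG channels sampled
   at 1000 Hz (7 upper-arm + 5 forearm muscles); each channel is normalized
   by its maximum over the training trials. The elbow goniometer angle is
   differentiated into angular velocity.
2. **Phase segmentation** — motion onset and reach end are the crossings of
   a threshold at 10 % of the subject's maximum angular velocity
   `v_thr = 0.1 · v_max`; phase 1 = onset → velocity peak, phase 2 =
   peak → reach end, phase 3 = a further 25 % of the reach duration.
3. **Features** — sliding 150 ms windows with a 50 ms step; per channel the
   mean activation, waveform length `Σ|x_{i+1} − x_i|`, and slope-sign
   changes (with a 1 % noise deadband).
4. **Decoders** — LDA (pooled covariance with Ledoit–Wolf shrinkage),
   linear and RBF SVMs (`C`, `γ` grid-searched by 4-fold trial-stratified
   cross-validation), and an echo state network driven by the raw
   envelopes, `x(t) = tanh(W_in u(t) + W x(t−1))` with the reservoir
   rescaled to spectral radius ρ and a ridge-regression readout.
   Protocol: per subject, 10 test + 20 train/validation trials per class.
5. **Decision** — per-window votes enter a 0.5 s majority-vote buffer; the
   grasp command fires when the winning class's vote fraction exceeds 0.5.
   Time-to-confidence (trigger latency from motion onset) is the latency
   metric.

Because the recorded human data are not public, the package ships a
synthetic trial generator (`reachgrasp.synthetic_data`) that emulates the
study conditions: minimum-jerk-like elbow extension with the velocity peak
at 30–45 % of the reach, able-bodied vs amputee activation profiles, and
per-phase class-specific muscle patterns. Every claim the package makes is
tested against this generator.

## Worked example

```python
from reachgrasp import (SynthConfig, generate_dataset, run_offline,
                        run_online_comparison, HyperParams)

trials = generate_dataset(SynthConfig(seed=1))        # 5 grasps x 30 trials
hp = HyperParams(svm_C=(1.0, 10.0), svm_gamma=(0.001, 0.01))

rep = run_offline(trials, "svm_rbf", hp=hp, seed=0)
print({ph: round(a, 3) for ph, a in rep.phase_accuracy.items()})

cmp = run_online_comparison(
    generate_dataset(SynthConfig(n_trials_per_class=45, seed=0)),
    seed=0, hp=hp, n_test=20, n_trainval=25,
)
print(round(cmp.report_all.accuracy, 2), round(cmp.report_third.accuracy, 2))
print(round(cmp.report_all.ttc.mean_s, 3), round(cmp.report_third.ttc.mean_s, 3))
```

prints

```
{1: 0.594, 2: 0.934, 3: 0.992}
0.9 0.72
0.37 0.516
```

Reading: the majority-vote accuracy of the RBF-SVM decoder rises from 59 %
in phase 1 (the arm is accelerating, class information is weakest) to 93 %
in phase 2 and 99 % in the post-reach hold. In the streamed online replay,
training on all motion phases yields 90 % correct grasp triggers at a mean
latency of 0.37 s after motion onset, whereas a decoder trained only on the
static hold (phase 3 — the conventional protocol) is both less accurate
(72 %) and slower (0.52 s): a decoder must see the reach to decode during
the reach.

A command-line interface mirrors the library:

```bash
reachgrasp simulate --out data/ --seed 1
reachgrasp segment --data data/ --out boundaries.csv
reachgrasp evaluate --data data/ --classifier svm_rbf --seed 0 --out report/eval
reachgrasp compare --data data/ --what online --seed 0 --out online.json
reachgrasp analyze-phases --data data/ --out phases/out
```

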