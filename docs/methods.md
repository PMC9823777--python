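# Methods

## Problem and model

`tsdval` estimates the *value* of every training sample in a windowed
multivariate time-series classification task — the motivating setting is
wearable-IMU human activity recognition (HAR), where labels come from manual
video annotation or clinical scoring and a nontrivial fraction of them is
wrong.  The value of sample (x, y) is defined as a selection probability
h_φ(x, y) ∈ (0, 1) produced by a *data value estimator* (DVE); the estimator
is trained so that selecting training samples with probability h_φ minimizes
the downstream classifier's validation loss.  Low values flag corrupted or
unhelpful samples.

Three networks cooperate:

1. **DVE** — a feature extractor (one 1D convolution, 64 filters, kernel 3,
   GeLU, plus sinusoidal positional encoding, followed by two transformer
   encoder blocks with 2 attention heads, feed-forward width 256, dropout
   0.1, GeLU, then global average pooling over time) feeds a 64-d embedding;
   the embedding concatenated with the one-hot label passes through five
   dense layers of 100 ReLU units; the *marginal information*
   m(x, y) = |y_onehot − f_v(x)| is concatenated after that MLP, so it
   reaches the output only through the final dense layer; a sigmoid squashes
   the final scalar and the result is clipped to [1e−6, 1 − 1e−6].
2. **Predictor f_θ** — a double-head 1D-CNN stacking ensemble: parallel
   convolutions with kernels 1 and 3 (64 filters, ReLU), global max pooling
   per head, concatenation, dense softmax classifier.  Trained with the
   value-weighted cross-entropy (1/B) Σ w_i · CE(f(x_i), y_i).  Its loss on
   the clean validation split is the reinforcement reward.
3. **f_v** — the same architecture trained on the validation split only and
   frozen; it supplies m(x, y), a per-class contamination signal that is
   near 0 for samples whose label agrees with clean evidence and near 1 in
   the disagreeing components of a flipped label.

Training is REINFORCE: per outer iteration, draw a selection batch, sample
binary selection vectors s ~ Bernoulli(h_φ), train the predictor on each
selection (N_I masked gradient steps at learning rate α), measure validation
loss L, and step the DVE along (L − δ) ∇ log π_φ(s), where
log π = Σ s log p + (1 − s) log(1 − p) and δ is a moving-average baseline
updated as δ ← ((T−1)/T) δ + L/T.  Both networks use Adam (β₁ = 0.9,
β₂ = 0.999, ε = 1e−8); defaults α = β = 0.01, N_I = 200 per evaluation,
30 outer iterations, T = 20, predictor batch B_p = 64 (small-data profile;
1024 is the large-data profile), selection batch B_s = min(N_train, 4·B_p).

All tensors are float64 on a numpy reverse-mode autodiff core (`tsdval.nn`)
written for this package; no GPU framework is used or needed at these sizes.

## Stabilizing the policy gradient at small iteration counts

The textbook loop — one Bernoulli draw per outer iteration, a predictor that
persists across iterations, baseline initialized at zero — is unstable at
small scale: with a strictly positive loss and δ starting at 0 the advantage
is positive for roughly T iterations, which uniformly suppresses whatever
was drawn; and once the mean selection probability collapses, the persistent
predictor keeps training on near-empty selections, its validation loss
explodes, and the collapse becomes absorbing.  We observed both failure
modes reproducibly on the synthetic conditions.  Five measures, none of
which changes the definition of the estimator or of the statistics, make the
gradient informative within ~15 outer iterations on one CPU:

* **Snapshot-restore evaluation.** The predictor is warm-started once on the
  full training split; before every selection evaluation it (and its Adam
  state) is restored to that snapshot, so the reward is a function of the
  current selection alone rather than of selection history.
* **Monte-Carlo draws with centred advantages.** `n_draws` (default 6)
  selection vectors are drawn per outer iteration and the surrogate is the
  mean over draws of a_k log π(s_k) with a_k = (L_k − δ) re-centred to zero
  mean within the draw batch (a leave-one-out-style baseline).  Because
  Σ_k a_k = 0, the component of the gradient common to all draws cancels
  exactly — only the contrast between selections (which draws contained
  corrupted samples) drives the update, which removes the collapse
  mechanism structurally rather than damping it.
* **Common random numbers.** All draws within an iteration share the
  inner-loop minibatch sequence, so reward differences between draws are
  attributable to the selections, not to minibatch ordering.
* **Warm baseline.** δ is initialized at the warm-start validation loss
  (its long-run target under null selections) instead of 0, centering early
  advantages.  The recursion itself is unchanged.
* **Guard rails.** The reward cross-entropy floors predicted class
  probabilities at 1e−3, bounding the advantage a single diverged inner run
  can produce (max ≈ ln K/floor instead of ~20+); a penalty
  1000 · (relu(mean p − 0.9) + relu(0.1 − mean p)) on the batch-mean
  selection probability blocks the two absorbing extremes; an all-zero
  selection draw is resampled up to 10 times and then the highest-probability
  sample is force-selected (the weighted loss is undefined on an empty
  selection).
* **Zero-initialized head.** The DVE's final dense layer starts at zero, so
  every sample's initial value is exactly 0.5 and the initial ranking
  carries no random bias from head initialization — the learned ordering is
  then attributable to training, which matters when few outer iterations
  are run.

With these in place the corrupted/clean value separation emerges reliably in
15 outer iterations on the synthetic conditions (all three test seeds), with
the discovery curve tracking the ideal curve.

## Evaluation statistics

**CSD** (corrupted-sample discovery): sort training samples ascending by
value (stable, index tie-break), accumulate the lowest v·r samples with
v = round(0.05 N) and r = 0…10, and report the fraction of the o injected
label flips contained in the accumulation.  The ideal curve is
min(v·r/o, 1); with 20 % corruption and 5 % steps it saturates at r = 4.
Under exchangeable (uninformative) values E[CSD_r] = v·r/N.  CSD is a rank
statistic: strictly monotone transformations of the values leave it
unchanged.

**RHLVS** (remove high/low-value samples): for r = 0…10 retrain a reference
classifier from scratch on the training split minus the v·r highest-
(resp. lowest-) valued samples, weighting each remaining sample by its value
(an `unweighted` switch trains plainly on the remainder), and record test
accuracy.  One shared seed per curve makes the r = 0 points of the two
directions coincide exactly.  Three classifier variants are built from two
conv/maxpool blocks (64 filters, kernel 3, ReLU, pool 2): GRU(8) head with
50 % dropout (clinical-data profile), flatten + dense head (public
baseline), GRU(8) head with 70 % dropout (public complex); all end in a
100-unit dense layer and softmax.  The two-conv-block depth is the minimal
realization consistent with the stated layer hyperparameters.

## Synthetic data generator

The generator emulates the gross structure of windowed IMU activity data:
class k carries a deterministic periodic signature — fundamental frequency
1.5 + k cycles per window, per-channel amplitudes cycling over
(1.0, 0.7, 0.5), a fixed per-channel phase stagger, and a second-harmonic
group of channels — plus i.i.d. Gaussian noise (default sd 0.3, ~⅓ of the
signature amplitude: separable classes, but enough overlap that corrupted
labels measurably hurt training).  Defaults follow the evaluation protocol:
3 classes × 90 windows (270 total), window length 64, 6 channels, a seeded
4:2:3 train/validation/test split (largest-remainder rounding, per-sample
assignment), and a corruption step that flips round(rate · N_train) training
labels (default rate 0.2) to a uniformly drawn *different* class, recording
ground truth for CSD.

What it does **not** emulate: real biomechanics, subject-level structure
(splits are per-sample, not per-subject), sensor drift/orientation effects,
class imbalance, or non-stationary noise.  Passing tests therefore show the
algorithm's mechanics are correct and that it recovers *injected* label
noise under controlled conditions — not that it attains any particular
performance on real recordings.

## Problem sizes and numerical choices

The test suite and the acceptance script run a compact single-CPU profile of
the protocol: N_I = 50, 15 outer iterations, 6 draws, 100 warm-start
iterations, and a 60-iteration public-baseline classifier for RHLVS — sizes
chosen so the full three-seed study completes in minutes while leaving the
algorithm enough iterations to separate corrupted from clean samples.  The
defaults on the config dataclasses keep the full protocol values (200
predictor iterations, 30 outer iterations).

Numerical details: float64 throughout; probability clip 1e−6 keeps the
Bernoulli log-likelihood finite; zero-variance channels normalize with
sd = 1 (warned) so constant channels map to ~0 rather than NaN; temporal
max pooling drops a trailing odd timestep; window labels from per-timestep
labels use majority vote with the midpoint label breaking ties; split-size
rounding uses largest remainders (deterministic, sums to N); decimation is
plain subsampling without an anti-aliasing filter.  Everything stochastic
flows through explicitly seeded numpy generators — identical configuration
and seed reproduce outputs bit-for-bit.

## Known limitations

* REINFORCE with a handful of outer iterations estimates a coarse ranking;
  values saturate toward the band edges under long training rather than
  converging to calibrated probabilities.
* The reward uses the full validation split each evaluation; very large
  validation sets would want subsampling.
* The oversampling augmentation is jitter-duplication (additive Gaussian
  noise scaled by per-channel training sd), a deliberately simple stand-in
  for the more elaborate augmentation pipelines used in the HAR literature.
* Per-sample (not per-subject) splitting overstates accuracy on data with
  strong subject effects; adapters for subject-wise splits are left to the
  caller.
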