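# Methods

## Problem setting

A single-lead ECG trace recorded at one auscultation site (Aortic,
Pulmonary, Tricuspid or Mitral chest position, or limb Lead I) is
reconstructed from traces recorded simultaneously at other sites.  The
reconstruction is framed as instantaneous regression: the amplitude of
the target channel at a sample is predicted from the amplitudes of the
input channels at the same sample, with no temporal windowing.  Because
an acquisition session captures only three channels at a time (Lead I,
ECGA, and one of ECGP/ECGT/ECGM), sessions are treated separately and
never mixed; within a session, every channel may serve as the target
with every non-empty subset of the remaining channels as inputs — nine
tasks per session, 27 across the three sessions.

The regressor is a fully connected network whose hyperparameters (depth,
per-layer width, activations, optimizer, loss, epoch budget) are tuned
in two stages: a budgeted uniform random search over a wide space,
followed by a Taguchi orthogonal-array experiment over the narrowed
space.

## Synthetic data generator

Real multichannel recordings of this kind are not freely
redistributable, so the package ships a generator that emulates their
two load-bearing properties: a shared heart rhythm across channels, and
site-to-site morphology differences that put pairwise Pearson
correlations in the 0.25–0.60 range.

* **Rhythm.**  RR intervals are drawn i.i.d. Gaussian around the mean
  heart rate (default 70 beats/min) with a fractional SD (default 3 %),
  truncated at ±3 SD and floored at 0.2 s.  A beat phase θ(t) sweeps
  (−π, π] linearly within each interval and is shared by all channels.
* **Morphology.**  Each beat is a phase-domain sum of five Gaussian
  kernels, one per P/Q/R/S/T wave — the standard dynamical-model
  parameterization of ECG morphology.  Defaults place the R wave at
  θ = 0 with unit amplitude; Q and S are negative.  A per-beat amplitude
  jitter (2 % SD) adds physiological variability.
* **Cross-channel correlation.**  Channel i mixes the common morphology
  c(t) with a channel-private morphology p_i(t) as
  λ·ĉ + (1−λ)·p̂_i (both standardized).  Private morphologies are drawn
  with perturbed wave parameters on the shared phase and then
  Gram-Schmidt-orthogonalized against the common source and against each
  other, so λ is the single knob controlling correlation and the map
  λ → r is continuous and non-decreasing for a fixed seed.
  `calibrate_correlation` bisects this map (all evaluations reuse one
  simulation, so the map is exactly monotone) to hit a target r within
  ±0.05 on ≥ 60 s of signal.
* **Noise.**  Per channel: white Gaussian noise (default SD 0.03),
  sinusoidal baseline wander (default 0.05 at 0.3 Hz) and powerline
  interference (default 0.01 at 50 Hz), each from an independent
  substream of the master seed so toggling one term never perturbs the
  others.  No quantitative noise characterization of the original
  recordings is available; these defaults are plausible relative levels
  for gel-electrode chest recordings and are freely configurable.

What the generator does **not** emulate: pathological morphologies,
respiration beyond the baseline-wander sinusoid, electrode-motion
artifacts, inter-subject variability, and the nonstationarity of real
recordings.  Tests passing on this generator therefore demonstrate the
correctness and internal consistency of the tuning machinery, not
clinical performance on real ECG.

## Preprocessing

Channels are low-pass filtered with a third-order Butterworth filter
applied forward-backward (zero phase, so wave morphology is not
shifted); the bidirectional pass squares the magnitude response, leaving
a tone at the cutoff at half amplitude.  The cutoff is picked per
channel from a candidate grid (default 20–80 Hz in 5 Hz steps, clamped
below Nyquist) by exhaustively maximizing
`SNR(fc) = 10·log10(P_pass / P_removed)`, where `P_pass` is the power of
the filtered signal and `P_removed` the power of the residual; ties
break toward the larger cutoff.  When a clean reference trace exists
(synthetic mode), a distortion penalty `κ·(1 − corr(reference,
filtered))²` (default κ = 10) can be added.  Note that for broadband
noise this criterion is non-decreasing in the cutoff, so on
white-noise-dominated inputs the automated choice tends to the widest
admissible band; the reference-penalized variant is the one that
meaningfully trades bandwidth against morphology distortion.

Signals are min-max normalized to [0, 1].  Normalization statistics are
computed on the training block only and reused for the test block to
avoid leakage; a constant signal normalizes to zeros with a warning.
The split is 80–20 and chronological by default (ECG samples are time
ordered); a seeded random split is available behind a flag.

## Network and training

Architectures are dense stacks of 3–8 hidden layers, 5–255 units each,
with per-layer activations from {relu, elu, selu, sigmoid, tanh,
linear} and a single linear output unit (a sigmoid head is available
behind a flag; "sigmoid in the final layer" is interpreted as the last
*hidden* layer).  The selu variant used here is
`f(x) = x for x > 0, α·β·(e^x − 1) otherwise` with α = 1.76, β = 1.05 —
note the positive branch is not scaled, unlike the canonical
self-normalizing SELU.

Training is minibatch gradient descent (batch 32, Glorot-uniform
initialization, float32) under SGD (lr 0.01), RMSProp (lr 0.001,
ρ 0.9) or Adam (lr 0.001) — the conventional default rates, recorded in
trial logs.  The loss is MSE or MAE; the `val_loss` objective trains on
MSE while model selection tracks the validation MSE, which every trial
does anyway: after each epoch the MSE on the held-out block is computed,
the weights of the best epoch are checkpointed, and training stops once
`patience = 10` epochs pass without a new best.  The checkpointed
weights are restored before test metrics are computed.  A non-finite
loss marks the trial failed (NaN metrics, ranked last) instead of
raising.  Everything is deterministic given (spec, data, seed).

Using the held-out 20 % block both for early stopping and for the
reported metrics mirrors the tuning protocol this package implements;
it is mildly optimistic, and a stricter three-way split can be obtained
by passing a separate validation pair.

## Metrics

R² = 1 − SSE/SST (not clipped; negative for worse-than-mean
predictors), MAE and MSE with 1/N normalization, and the sample SD of
the predicted trace with N−1 degrees of freedom.  The channel
correlation table is signed Pearson, reported as fractions.

## Two-stage tuning

**Stage 1 — random search.**  A fixed budget of configurations (200 in
the reference protocol) is drawn uniformly: each factor independently,
per-layer factors per layer.  Trials are ranked by test R² (error-metric
ranking available).  The 200-trial budget covers under 0.1 % of the
enumerable reference space.

**Narrowing.**  The top k = 10 trials are tallied factor by factor.
Categorical levels with top-k frequency below `min_freq = 0.1` are
dropped; a factor whose level frequencies stay within `min_freq` of each
other is treated as diverse and kept fully spread; every factor is
capped at its 4 most frequent levels so an orthogonal-array column can
host it, and the optimizer always collapses to its modal level (the
protocol fixes the optimizer after stage 1).  Per-layer activations are
tallied position-agnostically except the last hidden layer, which gets
its own factor.  Unit counts are re-bounded to the observed span and
snapped onto the level grid {10, 64, 100, 200}.

**Stage 2 — orthogonal array.**  The degrees of freedom of the narrowed
space (Σ levels−1 per factor) lower-bound the run count at dof + 1.  The
smallest array from the standard catalogue — L4, L8(2⁷), L9(3⁴),
L16(4⁵), L18(2¹3⁷), L25(5⁶), L27(3¹³), all built from finite-field
recipes and verified by an exhaustive strength-2 balance check — that
can host every factor is selected; factors with fewer levels than their
column repeat their first level (dummy-level technique).  Every run is
decoded into a concrete architecture and trained once (replicates
supported, replicate r reusing seed + r across runs).

**Main effects and prediction.**  Per factor and level: the mean
response over the runs at that level (replicates averaged per run
first) and the mean signal-to-noise ratio in dB (larger-the-better
−10·log₁₀(mean 1/y²) for R², smaller-the-better −10·log₁₀(mean y²) for
error metrics; non-positive R² responses are clipped at 1e−6 with a
warning).  Factor influence is ranked by delta (max − min of level
means).  The predicted best configuration takes each factor's level with
the best mean response, with mean S/N and then level index as
tie-breaks; level means are exact main-effect estimates for additive
response surfaces under the array's balance, so on such surfaces the
prediction coincides with the full-factorial argmax (verified
exhaustively in the tests).  A confirmation training of the predicted
configuration is always run and logged.

## Benchmarks and problem sizes

The package validates its own pipelines on two built-in desk-scale
benchmarks (`ecgtune.benchmarks`), both two-input/one-output tasks on
calibrated synthetic data:

* **Oracle comparison:** fs 500 Hz, 60 s, target correlation 0.6;
  a Taguchi experiment over a four-factor L9 space (depth {3,4,5},
  width {8,16,32}, body activation {relu,elu,selu}, epochs
  {10,100,200}; sigmoid final layer, RMSProp, MSE) is compared with the
  ordinary-least-squares reference on the same splits, over 3 seeds.
  Because the generator's channels are nonlinear functions of a shared
  beat phase, the tuned network typically *beats* the linear reference.
* **Method comparison:** fs 250 Hz, 20 s, target correlation 0.5;
  random-only search versus the narrowed + orthogonal-array pipeline at
  an equal total budget of 40 trainings per method, over 5 seeds.  The
  pipeline reserves 19 trainings for its final stage (enough for the
  worst-case L18 plus confirmation under 3-level narrowing), leaving 21
  for stage 1, so its final stage trains at most half as many networks
  as the random baseline while staying non-inferior in best test R².

These sizes (and the package-wide default of 500 Hz rather than a
laboratory-grade acquisition rate) were chosen so a complete validation
runs on one CPU in minutes; every dimension scales up through plain
parameters.

## Numerical choices and edge cases

* Bisection tolerance for correlation calibration: 1e−4 on λ.
* Filter edge effects: zero-phase filtering uses `sosfiltfilt` with its
  default padding; tone-attenuation tests trim 2 s edges.
* Ties in `adapt_cutoff` (including multiple +inf scores when the
  residual vanishes) resolve toward the larger cutoff.
* `minmax_normalize` of a constant signal returns zeros with a warning
  rather than raising, keeping batch pipelines alive.
* Orthogonal-array selection places factors greedily, largest level
  count first, each into the smallest sufficient unused column;
  infeasibility reports the largest offending factor.
* All randomness flows from `numpy.random.SeedSequence` substreams of a
  single master seed; derived integer seeds stay below 2³¹.

## Known limitations

* Per-sample regression ignores temporal context; architectures with
  memory (or lagged inputs) would likely dominate on real data.
* The single λ-per-channel correlation model cannot reproduce an
  arbitrary correlation matrix, only the one-parameter family used for
  calibration.
* The S/N-based cutoff adaptation degenerates to the widest band on
  white-noise-dominated inputs (see Preprocessing).
* Per-layer heterogeneous widths/activations are explored in stage 1
  but the array stage encodes width body-wide and activation as
  body + final-layer factors; a per-layer local refinement around the
  predicted best is a natural extension and is not implemented.
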