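# ecgtune

Reconstruction of a single-lead ECG trace at one auscultation site from
traces recorded at other sites, with the regression network's
hyperparameters optimized by a Taguchi orthogonal-array experiment.

Chest recordings of this kind come in sessions of three synchronized
channels — limb Lead I, the aortic-site trace (ECGA), and one of the
pulmonary/tricuspid/mitral traces (ECGP/ECGT/ECGM) — whose pairwise
Pearson correlations are only moderate (roughly 0.25–0.60), so linear
lead-reconstruction methods leave accuracy on the table.  `ecgtune`
frames the problem as instantaneous regression y(t) = f(x₁(t), x₂(t))
with a dense network f, and tunes f in two stages:

1. **Random search** — a fixed budget of architectures drawn uniformly
   from a wide space (3–8 hidden layers, 5–255 units per layer, six
   activation functions, three optimizers, MSE/MAE/validation-loss
   objectives, epoch budgets {10, 100, 200}), each trained with early
   stopping (patience 10) and best-epoch checkpointing, ranked by test
   R² = 1 − SSE/SST.
2. **Taguchi orthogonal array** — the factor levels that dominate the
   best trials define a narrowed space; its degrees of freedom
   (Σ (levels − 1)) select the smallest strength-2 orthogonal array from
   the standard catalogue (L4…L27); one training per run yields
   per-factor level means and signal-to-noise ratios
   (−10·log₁₀(mean 1/y²) for larger-the-better responses), whose
   per-factor optima assemble the predicted best configuration,
   validated by a confirmation run.

Because the real database is not redistributable, the package includes a
seedable synthetic multichannel ECG generator (shared beat-phase
process, five Gaussian wave kernels per beat, common/private morphology
mixing with a calibrated correlation knob, baseline-wander / powerline /
white noise) on which the whole pipeline is exercised and tested.

Intended users: biomedical-signal and ML researchers who want a
reproducible, inspectable implementation of orthogonal-array
hyperparameter tuning for signal reconstruction, and a controllable ECG
test bed to run it on.

## Worked example

```python
from ecgtune.benchmarks import (
    make_benchmark_task, l9_benchmark_space, linear_oracle_r2,
)
from ecgtune.taguchi import TaguchiExperiment

# two-input -> one-output task on synthetic data calibrated to
# inter-channel correlation 0.6 (fs 500 Hz, 60 s, 80-20 split)
train, test = make_benchmark_task(fs=500, duration=60, target_r=0.6, seed=1)
print(f"linear least-squares reference R2: {linear_oracle_r2(train, test):.4f}")

results = TaguchiExperiment(l9_benchmark_space(), train, test).fit(seed=1)
print(results.summary())
```

Output:

```
linear least-squares reference R2: 0.3277
Taguchi orthogonal-array experiment
  array: L9 (9 runs x 4 columns), replicates=1
  response: r2 (larger-the-better S/N)
  grand mean response: 0.6270

    factor level  mean_response  mean_sn_db  n_runs  delta  rank
     depth     3         0.6249     -4.0878       3 0.0032     4
     depth     4         0.6280     -4.0423       3 0.0032     4
     depth     5         0.6281     -4.0432       3 0.0032     4
     units     8         0.6244     -4.0941       3 0.0079     2
     units    16         0.6322     -3.9845       3 0.0079     2
     units    32         0.6243     -4.0946       3 0.0079     2
activation  relu         0.6240     -4.1003       3 0.0060     3
activation   elu         0.6269     -4.0586       3 0.0060     3
activation  selu         0.6300     -4.0144       3 0.0060     3
    epochs    10         0.6055     -4.3579       3 0.0335     1
    epochs   100         0.6390     -3.8895       3 0.0335     1
    epochs   200         0.6364     -3.9259       3 0.0335     1

predicted best: depth=5, units=16, activations=selu-selu-selu-selu-sigmoid, optimizer=rmsprop, loss=mse, epochs=100
confirmation run: R2=0.6425, MAE=0.0596, MSE=0.0065, SD=0.1084 (best epoch 41)
```

Reading it: nine trainings (an L9 array over depth, width, body
activation and epoch budget) estimate each factor's main effect; the
epoch budget matters most (delta 0.034, rank 1), depth barely matters on
this task.  The per-factor best levels assemble the predicted
configuration, whose confirmation run reaches R² = 0.64 — well above the
0.33 of the linear reference, because the channels are nonlinear
functions of a shared beat phase.

The command line mirrors the library:

```sh
ecgtune generate --channels LEAD1,ECGA,ECGP --fs 500 --duration 60 \
    --target-corr 0.5 --seed 7 --out rec.csv
ecgtune preprocess --in rec.csv --cutoff auto --out filtered.csv
ecgtune tune random --in filtered.csv --inputs LEAD1,ECGA --output ECGP \
    --budget 50 --seed 7 --log trials.jsonl
ecgtune narrow --log trials.jsonl --out narrowed.yaml
ecgtune tune taguchi --in filtered.csv --inputs LEAD1,ECGA --output ECGP \
    --space narrowed.yaml --seed 7 --report effects.csv
ecgtune pipeline --config config.yaml   # all stages, 27-task report
```

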