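# semgkit

Surface-electromyography (sEMG) hand-movement classification at the scale
of the public multi-subject prosthetics benchmarks: ~50 movement classes,
10 or 12 forearm electrodes, guided acquisitions of 5 s movement / 3 s
rest repetitions. The package is aimed at researchers in myoelectric
control who want a tested, fully synthetic-data-capable re-implementation
of the classic comparison between a small convolutional network on raw
signal windows and the standard feature-plus-classifier pipeline.

## What it does

- **Simulation** (`semgkit.synthetic`): Ninapro-style recordings with
  known ground truth — per-class channel activation patterns, subject
  reaction-time lags between stimulus and true activity, 50 Hz
  power-line interference with harmonics, both electrode families
  (pre-rectified envelopes at 100 Hz and raw signals at 2 kHz).
- **I/O** (`semgkit.io`): the MAT-container dialect of the public
  databases (including the relabeled `restimulus`/`rerepetition`
  variants) and a plain-text fixture format.
- **Conditioning** (`semgkit.preprocessing`): linear-interpolation
  stream synchronization, frequency-domain Hampel removal of power-line
  interference, offline label refinement with a generalized
  likelihood-ratio (GLR) variance change-point model, moving-RMS
  rectification, anti-aliased resampling to 200 Hz, zero-phase 1 Hz
  envelope smoothing, and three window-normalization modes.
- **Windowing** (`semgkit.segmentation`): 150 ms (network) / 200 ms
  (classical) windows, majority labeling, repetition-wise train/test
  splits (test repetitions {2, 5, 7} of 10, or {2, 5} of 6) and
  median-count class balancing.
- **Classical arm** (`semgkit.features`, `semgkit.baselines`): RMS,
  waveform length (WL), 20-bin ±3σ histogram (HIST), marginal discrete
  wavelet transform (mDWT, db7, 3 levels) and their z-scored
  combination, classified by random forest, RBF-SVM or k-NN.
- **Network arm** (`semgkit.cnn`): the five-block convolutional network
  — 32 full-electrode-row filters, 3×3 and 5×5 padded convolutions with
  average pooling, a k4×1 block reducing the map to 1×1 (k4 = 5 for
  15-sample windows, 9 for ~30-sample windows), and a 1×1 softmax
  classifier — trained by SGD (momentum 0.9, learning rate 0.001,
  weight decay 0.0005, batch 256) with Gaussian-noise training-set
  augmentation at 25 dB SNR. Implemented as a compact NumPy engine with
  analytic backward passes; fully deterministic under a fixed seed.
- **Evaluation** (`semgkit.evaluation`): per-window and per-class
  accuracy, top-k errors with deterministic tie-breaks, the chance level
  100/n_classes, accuracy-to-chance ratios, and across-subject
  mean ± SD aggregation.

The model at the core: a window **X** ∈ ℝ^(T×C) (T time samples, C
electrodes) is mapped through

B1: ReLU(W₁ ∗ X) with W₁ ∈ ℝ^(32×1×C) →
B2: avgpool₃,₃(ReLU(W₂ ∗ ·)) →
B3: avgpool₃,₁(ReLU(W₃ ∗ ·)) →
B4: ReLU(W₄ ∗ ·), k4 = ⌊(T−3)/3⌋+1 →
B5: softmax(W₅ ∗ · + b)

minimizing cross-entropy with L2 weight decay. Classical features are
per-channel blocks [mDWT | HIST | WL | RMS], z-scored by training-set
statistics only.

## Worked example

```python
from semgkit import benchmark, pipeline

res = pipeline.run_experiment(benchmark.smoke_config("cnn", seed=1))
print(f"accuracy {res.report.overall_accuracy:.1f}% "
      f"(chance {res.report.chance:.1f}%), "
      f"balanced {res.balanced_report.overall_accuracy:.1f}%")
```

prints

```
accuracy 56.6% (chance 16.7%), balanced 73.3%
```

— a 2-epoch network run on a tiny simulated session (5 movements + rest,
2 electrodes): well above the 16.7 % chance level of a balanced 6-class
problem, with the balanced figure scoring on a class-balanced test
subset. The same experiment from the shell:

```bash
semgkit run --config my_experiment.yaml
```

where the YAML mirrors `benchmark.smoke_config` (`synthetic:`,
`windows:`, `split:`, `cnn:` or `baseline:` blocks, one global `seed`).
`semgkit simulate` writes synthetic recordings to disk, `semgkit
features` exports feature tables, and Ninapro-format `.mat` files can be
passed via a `data: {paths: [...]}` block instead of `synthetic:`.

## Layout

```
src/semgkit/
  synthetic.py     # protocol + signature simulation
  io.py            # MAT-container / columnar-text recordings
  preprocessing.py # sync, Hampel, GLR relabel, rectify, resample, low-pass
  segmentation.py  # windows, repetition-wise split, balancing
  features.py      # RMS / WL / HIST / mDWT / combined
  baselines.py     # random forest, SVM, k-NN over features
  cnn.py, _net.py  # the five-block network + NumPy layer engine
  evaluation.py    # accuracy, top-k, chance, subject aggregation
  pipeline.py      # config-driven end-to-end experiments
  benchmark.py     # canonical desk-scale experiment definitions
  cli.py           # `semgkit` command group
docs/methods.md    # modeling assumptions, parameter choices, limitations
```
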