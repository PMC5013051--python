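# Methods

This note records the modeling assumptions, parameter choices and known
limitations behind `semgkit`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The classification problem

A guided sEMG acquisition prompts a subject to perform each of ~50 hand
movements for several 5 s repetitions separated by 3 s of rest, while 10
or 12 forearm electrodes record muscle activity. The task is to assign
each short signal window (150 ms for the network arm, 200 ms for the
classical arm) to one of the ~51 classes (movements + rest). Because the
class count is large, raw accuracies are low by construction; the
balanced chance level 100/n_classes (1.96 % at 51 classes) and the
accuracy-to-chance ratio are the comparable quantities.

Whole repetitions — never individual windows — are assigned to train or
test (repetitions {2, 5, 7} of 10, or {2, 5} of 6, are held out). This
prevents temporal leakage: adjacent windows of one repetition are highly
correlated, and splitting them across sets would inflate accuracy.

## Synthetic acquisitions

The generator emulates the *structure* of such recordings, not the
physiology of any particular subject population:

- **Class identity** is a per-class, per-channel gain vector
  `baseline * (1 + separation * u)`, `u ~ U(0,1)` per channel. The
  `separation` scalar is the single difficulty knob: 0 removes all class
  information (classifiers must fall to chance), 5 — the default "high"
  condition — makes windowed RMS vectors linearly separable.
- **Carrier**: for raw 2 kHz electrodes, zero-mean Gaussian noise
  band-passed to 20–450 Hz (the typical sEMG band) and
  amplitude-modulated by the gain envelope; for pre-rectified 100 Hz
  electrodes, the moving-RMS envelope (100 ms window) of such a
  modulated carrier. Rest baseline is fixed at amplitude 1, so gains are
  dimensionless SNR multiples.
- **Reaction lags**: the stimulus vector follows the nominal prompt
  timing, while true activity is delayed by a per-repetition lag drawn
  uniform(0.1 s, 0.5 s) — plausible human reaction times, large enough
  to make label refinement measurable. Onsets/offsets carry 100 ms
  linear amplitude ramps to avoid unphysical steps.
- **Interference**: an optional 50 Hz sinusoid with 1/h-decaying
  harmonics up to Nyquist, random phase per channel.

What the generator does **not** emulate: motor-unit firing statistics,
electrode crosstalk, fatigue and electrode-shift drift, within-class
execution variability beyond carrier noise, or any specific database's
amplitude distributions. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its stages interact as
designed — not that real-data accuracies are reproduced. Real
acquisitions in the distributed MAT dialect can be substituted through
`semgkit.io`.

## Conditioning chain

Order for the network arm (raw 2 kHz input): Hampel interference
removal → GLR relabeling → RMS rectification (100 ms) → resampling to
200 Hz → 1 Hz zero-phase low-pass. Pre-rectified 100 Hz input skips the
interference and rectification stages (those electrodes are shielded
and already emit envelopes) and stays at 100 Hz. The classical arm stops
after relabeling and keeps the native rate: its features are defined on
the conditioned raw signal, and the 200 Hz / 1 Hz steps exist only to
make envelope windows cheap and smooth for the network. The 1 Hz
low-pass is applied to the whole recording before windowing.

- **Hampel filter** (frequency-domain): around each harmonic of 50 Hz,
  magnitude-spectrum bins within ±2 Hz whose magnitude exceeds
  median + 3·1.4826·MAD of the neighboring ±20 Hz band are shrunk to the
  local median (phases kept). A time-domain Hampel cannot target
  narrowband interference, hence the spectral formulation. A *dominance
  guard* additionally requires an outlier to exceed 4× the local median:
  single noise bins in the Rayleigh tail of the magnitude distribution
  cross a 3-robust-sigma bound routinely (≈0.7 % of bins), and clipping
  them would measurably distort interference-free signals, whereas a
  real power-line tone protrudes by orders of magnitude. With the guard
  the filter is a near-identity off the interference bins while still
  attenuating an injected tone by >20 dB at its periodogram ordinate.
- **GLR relabeling**: within ±1.5 s of each nominal boundary, the onset
  (offset) is re-estimated by maximizing the generalized log-likelihood
  ratio of a two-regime zero-mean Gaussian model with distinct
  variances, ML-estimated on each side of the candidate change point and
  summed over channels; cumulative sums of squares make the scan linear
  in the search width. If the best split does not beat the single-regime
  model by 5 log-units per channel, the boundary stays nominal — this
  keeps constant-variance (e.g. zero-separation) recordings at their
  nominal labels instead of chasing noise. Segments shorter than twice
  the 50 ms minimum regime are left nominal with a warning. The exact
  algorithm of the original relabeling literature is not recoverable
  from its citations; the variance-change model is the dominant sEMG
  onset signature and its parameters are exposed for calibration.
- **Windowing**: majority stimulus id labels each window (ties to the
  smaller id), so boundary windows are kept; rest windows inherit the
  repetition of the preceding movement (leading rest: the following
  one), making the repetition-wise split total. Stride defaults to
  10 ms; the desk-scale benchmark uses 700 ms to hit its window budget.
- **Balancing** subsamples every class — in practice rest, which
  otherwise dominates — to the median movement-class window count, on
  training data only; test scores are reported both on all test windows
  and on a class-balanced test subset (the headline figure, since the
  chance level assumes balance).

## The network

Five blocks on a T×C window (C electrodes): B1 collapses the electrode
axis with 32 full-row (1×C) filters + ReLU; B2 is a 3-wide padded
convolution + ReLU + 3-wide average pool, stride 3 (valid); B3 a 5-wide
padded convolution + ReLU + 3-wide average pool, stride 1, same-padded
(pure smoothing); B4 a k4×1 valid convolution + ReLU that reduces the
temporal extent to 1; B5 a 1×1 convolution into softmax cross-entropy.
Once B1 collapses the channel axis, the nominal 3×3 / 5×5 / 3×3 shapes
clip to their temporal extents.

k4 is always computed from the shape chain, `k4 = ⌊(T−3)/3⌋+1`: 5 for
15-sample windows (150 ms at 100 Hz) and 9 for ~30-sample windows
(150 ms at 200 Hz less one edge sample) — the two canonical electrode
setups. The two stated B4 sizes cannot both arise from any fixed
integer stride convention applied to exactly 15- and 30-sample inputs
(a reduction-by-3 chain forces the two extents to differ by exactly 5),
so the package treats the chain as authoritative and reports
`k4_canonical` for the two reference sizes; a 30-sample window yields
k4 = 10 and trains identically. The exact padding/stride convention of
the original implementation is not recoverable from filter sizes alone;
the one above is the least-assumption convention consistent with both
stated B4 sizes and is documented rather than asserted as original.

**Training**: SGD with momentum 0.9, learning rate 0.001, weight decay
0.0005, batch size 256, 30 epochs — the reference regime; the reduced
benchmark trains 5 epochs. Epoch shuffling is seeded and the last
incomplete batch is kept (desk-scale sets are small; dropping it would
lose data). Everything is float64 NumPy on one thread, so a fixed seed
reproduces training bit-for-bit.

**Initialization** (`init_mode`): the default `scale_aware` mode draws
uniform weights with fan-in-scaled bounds — first layer
`sqrt(6/fan_in)·2/data_range` (bringing unnormalized envelope inputs to
unit order), hidden layers `2.5·sqrt(6/fan_in)`, classifier layer zero
(initial class probabilities exactly uniform, so early gradients are
unsaturated). The hidden gain of 2.5 was calibrated on a synthetic
validation proxy so the net makes visible progress within a few epochs
at the *fixed* 0.001 learning rate; smaller gains leave activations too
small to learn in a 5-epoch budget, larger ones saturate. A
`data_range` mode (one shared bound, `init_fraction` × data range, for
every layer) is retained for experimentation; a single shared bound
cannot condition all five layers at once because only the first layer
sees the raw data scale.

**Augmentation** duplicates the training set and adds white Gaussian
noise rescaled per window so the realized SNR is exactly 25 dB relative
to that window's measured power ("SNR 25" is interpreted in decibels —
the conventional additive-noise reading; a linear power-ratio option is
exposed). Originals are kept verbatim; augmentation never touches test
data.

## Classical features

Per channel and window: RMS; waveform length (sum of absolute successive
differences); a 20-bin histogram spanning the window's own mean ± 3σ
with out-of-range samples clipped into the edge bins (self-normalizing
across electrodes; raw counts by default, frequencies as an option); and
the mDWT — sums of absolute detail coefficients of a db7 wavelet at
levels 1–3 plus the level-3 approximation marginal (the final
approximation retains low-frequency energy; it is included and
configurable). The DWT uses zero-padding extension, equivalent to plain
full convolution with the decomposition filters downsampled at odd
indices — the convention the test oracles implement independently. The
combined feature is the per-channel concatenation [mDWT | HIST | WL |
RMS], each dimension z-scored by training-set statistics only
(leakage-free). Windows must be at least 104 samples long for a 3-level
db7 decomposition, which the 200 ms classical window satisfies at 2 kHz;
at 100 Hz the mDWT is unavailable at that window length and the reader
is told the required length.

Note the edge bins of the histogram hold both the clipped tail mass
(|z|>3) and their own [2.7σ, 3σ) span — about 0.69 % of samples for
Gaussian data, not the 0.27 % tail alone.

## Baselines

Random forest (100 trees), RBF-kernel SVM (one-vs-one, C and γ selected
by a small grid on one held-out training repetition when not given) and
k-NN (k = 1), all seeded scikit-learn estimators. The source literature
cites these classifiers without hyperparameters; the defaults follow
common practice on this problem family and are explicitly
non-authoritative.

## Desk-scale benchmark and problem sizes

`benchmark.benchmark_config` defines the reduced 51-class condition used
by the acceptance checks: 50 movements + rest, 6 repetitions of 5 s/3 s
at 2 kHz on 12 channels (a ~40-minute simulated session), interference
amplitude 0.5, lags U(0.1, 0.5) s, 700 ms stride (≈42 windows per
movement class, ≈28 of them in training), 5 training epochs for the
network arm, random forest on combined features for the classical arm.
Scores are reported on the class-balanced test subset (~714 windows).
At separation 5 both arms score far above ten times chance; at
separation 0 both fall inside the exact-binomial 99 % band around
1/51 — the two checks that the pipeline neither loses class information
nor invents it. The network's per-class behavior at this budget is
uneven: rest, the one low-amplitude class, is learned last and often
still misclassified after 5 epochs, which depresses the unbalanced
(rest-heavy) score relative to the balanced one; 30-epoch runs resolve
it.

## Numerical choices and degenerate inputs

- Zero-phase filtering (`sosfiltfilt`) everywhere a filter touches
  labeled data, so labels never shift against the signal.
- Resampling is polyphase with built-in anti-aliasing; label vectors are
  transferred by nearest-sample index.
- Normalization and feature z-scoring guard zero variances with an
  epsilon and log a warning; constant windows survive every mode.
- Histogram σ = 0 puts all counts in the center bin; zero-power windows
  are copied unperturbed by augmentation; top-k ties break toward the
  lowest class id; subject SD uses the n−1 denominator.
- Seeds: one global experiment seed fans out to per-stage seeds via
  `SeedSequence.spawn`; all derived seeds stay below 2³¹.

## Limitations

- Synthetic data only exercises structure (see above); reported
  benchmark accuracies say nothing about accuracies on real recordings,
  which depend on electrode placement, subject condition and class
  taxonomy.
- MAT v7.3 (HDF5) containers are not read; re-save as v7 or earlier.
- The kinematics/dynamics streams of real acquisitions are carried as
  opaque extras, never synchronized or interpreted.
- The NumPy engine is single-threaded by design (determinism over
  speed); it is sized for desk-scale experiments, not GPU-scale
  replication of full-database training runs.
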