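"""Signal conditioning for sEMG recordings.

The chain mirrors a standard myoelectric-classification preparation:

1. ``synchronize_streams`` — linear-interpolation super-sampling of all
   streams to the highest sampling rate.
2. ``hampel_powerline_filter`` — frequency-domain Hampel outlier
   rejection of 50 Hz power-line interference and its harmonics
   (raw, unshielded electrodes only).
3. ``relabel_glr`` — offline refinement of stimulus-derived labels to the
   subject's actual, reaction-lagged activity boundaries with a
   generalized likelihood-ratio change-point statistic.
4. ``rms_rectify`` — moving root-mean-square envelope (makes raw 2 kHz
   signals comparable to electrodes that emit a rectified envelope).
5. ``resample_to`` — anti-aliased rate conversion (e.g. 2 kHz -> 200 Hz).
6. ``lowpass_envelope`` — zero-phase 1 Hz Butterworth smoothing of the
   envelope for the convolutional-network branch.
7. ``normalize_windows`` — optional window- or training-statistics
   normalization.

Two branch helpers fix the stage order: the convolutional branch is
sync -> Hampel (raw only) -> relabel -> rectify (raw only) -> resample to
200 Hz -> low-pass 1 Hz; the classical-feature branch stops after the
relabeling step and keeps the native rate, since the classical features
define their own windowing on the conditioned raw signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .types import Recording, WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "synchronize_streams",
    "hampel_powerline_filter",
    "relabel_glr",
    "rms_rectify",
    "resample_to",
    "resample_labels",
    "lowpass_envelope",
    "normalize_windows",
    "compute_window_stats",
    "preprocess_for_cnn",
    "preprocess_for_classical",
]


@dataclass
class PreprocessConfig:
    """Parameters of the conditioning chain.

    ``cnn_rate`` / ``cnn_lowpass_cutoff`` apply only to the
    convolutional branch.  ``normalization_mode`` is one of ``none``,
    ``per_window`` and ``train_stats``; the default is ``none``, which
    empirically performs best for this kind of envelope input.
    """

    target_sync_rate: float | None = None
    powerline_base: float = 50.0
    n_harmonics: int | None = None
    hampel_n_sigmas: float = 3.0
    hampel_bin_halfwidth: float = 2.0
    relabel_margin: float = 1.5
    relabel_min_llr_per_channel: float = 5.0
    rectify_window: float = 0.1
    cnn_rate: float = 200.0
    cnn_lowpass_cutoff: float = 1.0
    normalization_mode: str = "none"

    def __post_init__(self) -> None:
        if self.rectify_window <= 0:
            raise ValueError("rectify_window must be positive")
        if self.normalization_mode not in ("none", "per_window", "train_stats"):
            raise ValueError(f"unknown normalization_mode {self.normalization_mode!r}")


# ---------------------------------------------------------------------------
# synchronization


def synchronize_streams(
    streams: list[tuple[np.ndarray, float]], target_rate: float
) -> list[np.ndarray]:
    """Super-sample all streams to ``target_rate`` by linear interpolation.

    Streams are ``(signal, rate)`` pairs covering the same time span
    (span taken as ``(n - 1) / rate``).  All outputs share one length; a
    stream already at the target rate and length is returned unchanged.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if not streams:
        raise ValueError("need at least one stream")
    spans = []
    for x, rate in streams:
        x = np.asarray(x)
        if x.shape[0] < 2:
            raise ValueError("streams must have at least 2 samples")
        if rate > target_rate:
            raise ValueError("target_rate must be >= every input rate")
        spans.append((x.shape[0] - 1) / rate)
    span = max(spans)
    n_out = int(round(span * target_rate)) + 1
    t_out = np.arange(n_out) / target_rate

    out = []
    for x, rate in streams:
        x = np.asarray(x, dtype=float)
        if rate == target_rate and x.shape[0] == n_out:
            out.append(x)
            continue
        t_in = np.arange(x.shape[0]) / rate
        if x.ndim == 1:
            out.append(np.interp(t_out, t_in, x))
        else:
            cols = [np.interp(t_out, t_in, x[:, c]) for c in range(x.shape[1])]
            out.append(np.column_stack(cols))
    return out


# ---------------------------------------------------------------------------
# power-line interference


def hampel_powerline_filter(
    x: np.ndarray,
    rate: float,
    base: float = 50.0,
    n_harmonics: int | None = None,
    n_sigmas: float = 3.0,
    bin_halfwidth: float = 2.0,
    neighbor_halfwidth: float = 20.0,
    min_ratio: float = 4.0,
) -> np.ndarray:
    """Remove narrowband interference at ``base`` Hz and harmonics.

    Works on the magnitude spectrum: around each harmonic, bins within
    ``bin_halfwidth`` Hz whose magnitude exceeds the Hampel bound
    (median + ``n_sigmas`` * scaled MAD of the neighboring
    ``neighbor_halfwidth`` Hz band) are shrunk to the local median
    magnitude, phases untouched, and the signal is rebuilt by inverse
    transform.  Broadband content is left intact, so out-of-band power is
    preserved.

    ``min_ratio`` is a dominance guard: a bin is treated as interference
    only if it also exceeds ``min_ratio`` times the local median.  Single
    noise bins in the Rayleigh tail regularly cross a 3-robust-sigma
    bound, so without the guard an interference-free signal would be
    visibly altered; a genuine power-line tone protrudes an order of
    magnitude and is unaffected by the guard.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("hampel_powerline_filter operates on a single channel")
    nyq = rate / 2.0
    if base >= nyq:
        raise ValueError(f"base frequency {base} Hz is not below Nyquist ({nyq} Hz)")
    n = x.size
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mag = np.abs(spectrum)

    h = 1
    while True:
        f = base * h
        if f >= nyq or (n_harmonics is not None and h > n_harmonics):
            break
        target = np.abs(freqs - f) <= bin_halfwidth
        neighbor = (np.abs(freqs - f) <= neighbor_halfwidth) & ~target
        if target.any() and neighbor.any():
            med = np.median(mag[neighbor])
            mad = np.median(np.abs(mag[neighbor] - med))
            bound = max(med + n_sigmas * 1.4826 * mad, min_ratio * med)
            outliers = target & (mag > bound)
            if outliers.any():
                scale = med / np.maximum(mag[outliers], 1e-300)
                spectrum[outliers] *= scale
        h += 1
    return np.fft.irfft(spectrum, n=n)


# ---------------------------------------------------------------------------
# GLR relabeling


def _segments(stimulus: np.ndarray, repetition: np.ndarray):
    """Contiguous movement segments as (start, end, class, repetition)."""
    stim = np.asarray(stimulus)
    boundaries = np.flatnonzero(np.diff(stim) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [stim.size]])
    out = []
    for s, e in zip(starts, ends):
        if stim[s] > 0:
            out.append((int(s), int(e), int(stim[s]), int(repetition[s])))
    return out


def _glr_boundary(
    cum_sq: np.ndarray,
    lo: int,
    hi: int,
    a: int,
    b: int,
    min_regime: int,
    min_llr: float,
    nominal: int,
) -> int:
    """Best two-regime change point in [lo, hi] within context [a, b).

    ``cum_sq`` is the per-channel cumulative sum of squared samples with a
    leading zero row.  The two-regime model is zero-mean Gaussian with
    distinct variances left/right of the candidate, ML-estimated on each
    side, log-likelihood summed over channels.  Falls back to ``nominal``
    when the best split does not beat the single-regime model by
    ``min_llr`` (flat-GLR guard).
    """
    lo = max(lo, a + min_regime)
    hi = min(hi, b - min_regime)
    if hi <= lo:
        return nominal
    t = np.arange(lo, hi)
    n_left = (t - a).astype(float)
    n_right = (b - t).astype(float)
    eps = 1e-12
    sq_left = cum_sq[t] - cum_sq[a]
    sq_right = cum_sq[b] - cum_sq[t]
    var_left = np.maximum(sq_left / n_left[:, None], eps)
    var_right = np.maximum(sq_right / n_right[:, None], eps)
    ll_split = -0.5 * (
        n_left[:, None] * np.log(var_left) + n_right[:, None] * np.log(var_right)
    ).sum(axis=1)
    n_all = float(b - a)
    var_all = np.maximum((cum_sq[b] - cum_sq[a]) / n_all, eps)
    ll_single = -0.5 * (n_all * np.log(var_all)).sum()
    best = int(np.argmax(ll_split))
    if ll_split[best] - ll_single < min_llr:
        return nominal
    return int(t[best])


def relabel_glr(
    recording: Recording,
    search_margin: float = 1.5,
    min_regime: float = 0.05,
    min_llr_per_channel: float = 5.0,
) -> Recording:
    """Refine stimulus/repetition boundaries to the actual activity.

    For each nominal movement segment the onset and offset are
    re-estimated within +-``search_margin`` seconds by maximizing the
    generalized log-likelihood ratio of a two-regime variance model
    (rest variance vs. activity variance, summed over channels).  Class
    and repetition ids and the segment count are preserved.  Segments too
    short for the statistic, or where the GLR is flat (no detectable
    variance change, e.g. zero class separation), keep their nominal
    boundaries.
    """
    fs = recording.sampling_rate
    n = recording.n_samples
    margin = int(round(search_margin * fs))
    min_reg = max(int(round(min_regime * fs)), 2)
    min_llr = min_llr_per_channel * recording.n_channels

    segs = _segments(recording.stimulus, recording.repetition)
    # cumulative per-channel sum of squares, leading zero row
    cum_sq = np.concatenate(
        [np.zeros((1, recording.n_channels)), np.cumsum(recording.emg**2, axis=0)]
    )

    new_stim = np.zeros(n, dtype=int)
    new_rep = np.zeros(n, dtype=int)
    prev_end = 0
    for i, (s, e, k, r) in enumerate(segs):
        if e - s < 2 * min_reg:
            logger.warning(
                "segment %d (class %d rep %d) shorter than twice the minimum "
                "regime length; kept at nominal boundaries", i, k, r
            )
            onset, offset = s, e
        else:
            next_start = segs[i + 1][0] if i + 1 < len(segs) else n
            a_on = max(prev_end, s - 2 * margin, 0)
            b_on = min(s + 2 * margin, e)
            onset = _glr_boundary(
                cum_sq, s - margin, s + margin, a_on, b_on, min_reg, min_llr, s
            )
            a_off = max(e - 2 * margin, onset + 1)
            b_off = min(e + 2 * margin, next_start + margin, n)
            offset = _glr_boundary(
                cum_sq, e - margin, e + margin, a_off, b_off, min_reg, min_llr, e
            )
            if offset <= onset:
                onset, offset = s, e
        onset = max(onset, prev_end)
        new_stim[onset:offset] = k
        new_rep[onset:offset] = r
        prev_end = offset

    out = recording.with_labels(new_stim, new_rep)
    out.subject_meta = dict(recording.subject_meta)
    out.subject_meta["label_source"] = "relabeled"
    return out


# ---------------------------------------------------------------------------
# envelopes, resampling, smoothing


def rms_rectify(x: np.ndarray, rate: float, window: float = 0.1) -> np.ndarray:
    """Centered moving root-mean-square envelope (nonnegative)."""
    if window <= 0:
        raise ValueError("window must be positive")
    size = int(round(window * rate))
    if size < 2:
        raise ValueError(f"window of {window}s is shorter than 2 samples at {rate} Hz")
    x = np.asarray(x, dtype=float)
    squared = uniform_filter1d(x * x, size=size, axis=0, mode="nearest")
    return np.sqrt(np.maximum(squared, 0.0))


def resample_to(x: np.ndarray, rate_from: float, rate_to: float) -> np.ndarray:
    """Rate conversion with polyphase anti-alias filtering."""
    if rate_from <= 0 or rate_to <= 0:
        raise ValueError("rates must be positive")
    if rate_from == rate_to:
        return np.asarray(x, dtype=float)
    frac = Fraction(rate_to / rate_from).limit_denominator(10000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator, axis=0)


def resample_labels(labels: np.ndarray, rate_from: float, rate_to: float, n_out: int) -> np.ndarray:
    """Nearest-sample label transfer onto a resampled time base."""
    idx = np.round(np.arange(n_out) * rate_from / rate_to).astype(int)
    idx = np.clip(idx, 0, labels.size - 1)
    return np.asarray(labels)[idx]


def lowpass_envelope(x: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass (forward-backward)."""
    if cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({rate / 2.0} Hz)")
    sos = sps.butter(2, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


# ---------------------------------------------------------------------------
# window normalization


def compute_window_stats(windows: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std pooled over all training windows and samples."""
    flat = windows.samples.reshape(-1, windows.n_channels)
    return flat.mean(axis=0), flat.std(axis=0)


def normalize_windows(
    windows: WindowSet,
    mode: str = "none",
    train_stats: tuple[np.ndarray, np.ndarray] | None = None,
    eps: float = 1e-8,
) -> WindowSet:
    """Normalize window samples.

    ``none`` is the identity; ``per_window`` standardizes each window to
    mean 0 / std 1 (all channels pooled); ``train_stats`` applies
    per-channel mean/std computed from *training* windows only (pass the
    output of :func:`compute_window_stats`).  Zero standard deviations are
    epsilon-guarded.
    """
    if mode == "none":
        return windows
    if mode == "per_window":
        x = windows.samples
        mean = x.mean(axis=(1, 2), keepdims=True)
        std = x.std(axis=(1, 2), keepdims=True)
        if np.any(std < eps):
            logger.warning("constant window(s) in per_window normalization; epsilon guard used")
        return windows.with_samples((x - mean) / np.maximum(std, eps))
    if mode == "train_stats":
        if train_stats is None:
            raise ValueError("mode 'train_stats' requires statistics from training windows")
        mean, std = train_stats
        if np.any(std < eps):
            logger.warning("zero-variance channel in train_stats normalization; epsilon guard used")
        return windows.with_samples((windows.samples - mean) / np.maximum(std, eps))
    raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# branch pipelines


def preprocess_for_cnn(
    recording: Recording, config: PreprocessConfig | None = None
) -> tuple[Recording, list[str]]:
    """Conditioning chain for the convolutional branch.

    Raw 2 kHz recordings: Hampel -> GLR relabel -> RMS rectify ->
    resample to ``cnn_rate`` -> low-pass at ``cnn_lowpass_cutoff``.
    Pre-rectified 100 Hz recordings skip the interference and
    rectification stages (shielded electrodes already emit an envelope)
    and stay at their native rate when it is below ``cnn_rate``.
    """
    cfg = config or PreprocessConfig()
    log: list[str] = []
    rec = recording

    if rec.electrode_model == "raw_2khz":
        emg = np.column_stack(
            [
                hampel_powerline_filter(
                    rec.emg[:, c],
                    rec.sampling_rate,
                    base=cfg.powerline_base,
                    n_harmonics=cfg.n_harmonics,
                    n_sigmas=cfg.hampel_n_sigmas,
                    bin_halfwidth=cfg.hampel_bin_halfwidth,
                )
                for c in range(rec.n_channels)
            ]
        )
        rec = rec.with_emg(emg)
        log.append(f"hampel: base {cfg.powerline_base} Hz at {rec.sampling_rate} Hz")

    rec = relabel_glr(
        rec,
        search_margin=cfg.relabel_margin,
        min_llr_per_channel=cfg.relabel_min_llr_per_channel,
    )
    log.append(f"relabel_glr: margin {cfg.relabel_margin}s")

    if rec.electrode_model == "raw_2khz":
        rec = rec.with_emg(rms_rectify(rec.emg, rec.sampling_rate, cfg.rectify_window))
        log.append(f"rms_rectify: window {cfg.rectify_window}s")

    if rec.sampling_rate > cfg.cnn_rate:
        emg = resample_to(rec.emg, rec.sampling_rate, cfg.cnn_rate)
        stim = resample_labels(rec.stimulus, rec.sampling_rate, cfg.cnn_rate, emg.shape[0])
        rep = resample_labels(rec.repetition, rec.sampling_rate, cfg.cnn_rate, emg.shape[0])
        rec = Recording(
            emg=emg,
            stimulus=stim,
            repetition=rep,
            sampling_rate=cfg.cnn_rate,
            electrode_model=rec.electrode_model,
            subject_meta=dict(rec.subject_meta),
            extras=rec.extras,
        )
        log.append(f"resample: -> {cfg.cnn_rate} Hz ({emg.shape[0]} samples)")

    rec = rec.with_emg(lowpass_envelope(rec.emg, cfg.cnn_lowpass_cutoff, rec.sampling_rate))
    log.append(f"lowpass: {cfg.cnn_lowpass_cutoff} Hz at {rec.sampling_rate} Hz")
    return rec, log


def preprocess_for_classical(
    recording: Recording, config: PreprocessConfig | None = None
) -> tuple[Recording, list[str]]:
    """Conditioning chain for the classical-feature branch.

    Interference removal (raw electrodes only) and GLR relabeling; the
    signal keeps its native rate and raw form, since the classical
    features are computed on the conditioned signal directly.
    """
    cfg = config or PreprocessConfig()
    log: list[str] = []
    rec = recording
    if rec.electrode_model == "raw_2khz":
        emg = np.column_stack(
            [
                hampel_powerline_filter(
                    rec.emg[:, c],
                    rec.sampling_rate,
                    base=cfg.powerline_base,
                    n_harmonics=cfg.n_harmonics,
                    n_sigmas=cfg.hampel_n_sigmas,
                    bin_halfwidth=cfg.hampel_bin_halfwidth,
                )
                for c in range(rec.n_channels)
            ]
        )
        rec = rec.with_emg(emg)
        log.append(f"hampel: base {cfg.powerline_base} Hz at {rec.sampling_rate} Hz")
    rec = relabel_glr(
        rec,
        search_margin=cfg.relabel_margin,
        min_llr_per_channel=cfg.relabel_min_llr_per_channel,
    )
    log.append(f"relabel_glr: margin {cfg.relabel_margin}s")
    return rec, log
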