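"""Classical sEMG window features: RMS, waveform length, histogram and
marginal discrete wavelet transform, plus their normalized combination.

All extractors are deterministic and channel-separable: each channel of a
window contributes its own feature block, and permuting channels permutes
the blocks identically.  Feature vectors carry a ``names`` layout
(``ch03_hist_bin12`` style) so classifiers can verify at prediction time
that they see the layout they were trained on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .types import WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "feature_rms",
    "feature_wl",
    "feature_hist",
    "feature_mdwt",
    "feature_combined",
    "compute_feature_stats",
    "extract_features",
]


@dataclass
class FeatureSet:
    """Feature matrix with a named layout and carried-over labels."""

    values: np.ndarray  # (n_windows, n_features)
    names: list[str]
    labels: np.ndarray
    repetitions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.names):
            raise ValueError("values/names dimension mismatch")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def select(self, index: np.ndarray) -> "FeatureSet":
        index = np.asarray(index)
        return FeatureSet(
            values=self.values[index],
            names=list(self.names),
            labels=self.labels[index],
            repetitions=self.repetitions[index],
        )

    def to_delimited(self, path, delimiter: str = "\t") -> None:
        """Export as delimited text with a header naming each dimension."""
        header = delimiter.join(["label", "repetition"] + self.names)
        body = np.column_stack([self.labels, self.repetitions, self.values])
        np.savetxt(path, body, delimiter=delimiter, header=header, fmt="%.10g")


def _wrap(windows: WindowSet, per_channel: np.ndarray, feature_names: list[str]) -> FeatureSet:
    """Assemble (n, C, d) per-channel features into a flat FeatureSet."""
    n, n_ch, d = per_channel.shape
    names = [
        f"ch{c:02d}_{fname}" for c in range(n_ch) for fname in feature_names
    ]
    return FeatureSet(
        values=per_channel.reshape(n, n_ch * d),
        names=names,
        labels=windows.labels.copy(),
        repetitions=windows.repetitions.copy(),
    )


def feature_rms(windows: WindowSet) -> FeatureSet:
    """Root mean square per channel (1 value/channel)."""
    if windows.window_length < 1:
        raise ValueError("empty windows")
    vals = np.sqrt(np.mean(windows.samples**2, axis=1))  # (n, C)
    return _wrap(windows, vals[:, :, None], ["rms"])


def feature_wl(windows: WindowSet) -> FeatureSet:
    """Waveform length: sum of absolute successive differences."""
    if windows.window_length < 2:
        raise ValueError("waveform length requires at least 2 samples per window")
    vals = np.abs(np.diff(windows.samples, axis=1)).sum(axis=1)
    return _wrap(windows, vals[:, :, None], ["wl"])


def feature_hist(
    windows: WindowSet, n_bins: int = 20, sigma_mult: float = 3.0, density: bool = False
) -> FeatureSet:
    """Per-channel amplitude histogram over mean +- ``sigma_mult`` sigma.

    Each channel of each window is binned into ``n_bins`` equal-width bins
    spanning its own mean +- ``sigma_mult`` standard deviations;
    out-of-range samples are clipped into the edge bins, so counts always
    sum to the window length.  A constant channel (sigma = 0) puts all
    mass in the center bin.  With ``density=True`` counts are divided by
    the window length.
    """
    if windows.window_length < 2:
        raise ValueError("histogram requires at least 2 samples per window")
    x = windows.samples  # (n, w, C)
    n, w, n_ch = x.shape
    mean = x.mean(axis=1, keepdims=True)
    std = x.std(axis=1, keepdims=True)
    degenerate = std[:, 0, :] <= 0
    if degenerate.any():
        logger.warning("constant channel(s) in histogram feature; mass placed in center bin")
    # map to bin index: [-sigma_mult*std, +sigma_mult*std] -> [0, n_bins)
    safe_std = np.where(std > 0, std, 1.0)
    unit = (x - mean) / (sigma_mult * safe_std)  # [-1, 1] in range
    idx = np.floor((unit + 1.0) * 0.5 * n_bins).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)
    idx = np.where(np.broadcast_to(degenerate[:, None, :], idx.shape), n_bins // 2, idx)

    flat = (
        np.arange(n)[:, None, None] * (n_ch * n_bins)
        + np.arange(n_ch)[None, None, :] * n_bins
        + idx
    )
    counts = np.bincount(flat.ravel(), minlength=n * n_ch * n_bins).reshape(n, n_ch, n_bins)
    vals = counts.astype(float)
    if density:
        vals /= w
    return _wrap(windows, vals, [f"hist_bin{b:02d}" for b in range(n_bins)])


def mdwt_min_length(wavelet: str = "db7", levels: int = 3) -> int:
    """Smallest window length admitting a ``levels``-deep decomposition."""
    flen = pywt.Wavelet(wavelet).dec_len
    return (flen - 1) * 2**levels


def feature_mdwt(windows: WindowSet, wavelet: str = "db7", levels: int = 3) -> FeatureSet:
    """Marginal discrete wavelet transform.

    Per channel: the sum of absolute detail coefficients at each
    decomposition level 1..``levels`` plus the sum of absolute
    approximation coefficients at the deepest level
    (``levels + 1`` values/channel), computed with zero-padding
    extension.  All marginals are nonnegative and homogeneous of degree 1
    in the signal amplitude.
    """
    need = mdwt_min_length(wavelet, levels)
    if windows.window_length < need:
        raise ValueError(
            f"window length {windows.window_length} too short for a {levels}-level "
            f"{wavelet} decomposition; need at least {need} samples"
        )
    coeffs = pywt.wavedec(windows.samples, wavelet, mode="zero", level=levels, axis=1)
    # coeffs = [cA_L, cD_L, ..., cD_1]
    blocks = [np.abs(c).sum(axis=1) for c in coeffs[:0:-1]]  # d1 .. dL
    blocks.append(np.abs(coeffs[0]).sum(axis=1))  # a_L
    vals = np.stack(blocks, axis=2)  # (n, C, levels+1)
    names = [f"mdwt_d{l}" for l in range(1, levels + 1)] + [f"mdwt_a{levels}"]
    return _wrap(windows, vals, names)


def _reorder_per_channel(fs: FeatureSet, n_ch: int) -> np.ndarray:
    d = fs.values.shape[1] // n_ch
    return fs.values.reshape(fs.values.shape[0], n_ch, d)


def feature_combined(
    windows: WindowSet,
    train_stats: tuple[np.ndarray, np.ndarray] | None = None,
    n_bins: int = 20,
    sigma_mult: float = 3.0,
    wavelet: str = "db7",
    levels: int = 3,
    eps: float = 1e-8,
) -> FeatureSet:
    """Normalized combination [mDWT | HIST | WL | RMS] per channel.

    When ``train_stats`` (per-dimension mean/std from *training*
    features, see :func:`compute_feature_stats`) is given, every
    dimension is z-scored by it; pass ``None`` to obtain raw values, e.g.
    to compute the training statistics themselves.  Combined length is
    ``n_channels * (levels + 1 + n_bins + 1 + 1)``.
    """
    n_ch = windows.n_channels
    parts = [
        feature_mdwt(windows, wavelet=wavelet, levels=levels),
        feature_hist(windows, n_bins=n_bins, sigma_mult=sigma_mult),
        feature_wl(windows),
        feature_rms(windows),
    ]
    per_channel = np.concatenate([_reorder_per_channel(p, n_ch) for p in parts], axis=2)
    names_per_ch: list[str] = []
    for p in parts:
        d = len(p.names) // n_ch
        names_per_ch += [name.split("_", 1)[1] for name in p.names[:d]]
    out = _wrap(windows, per_channel, names_per_ch)
    if train_stats is not None:
        mean, std = train_stats
        if np.any(std < eps):
            logger.warning("zero-variance feature dimension(s); epsilon guard used")
        out.values = (out.values - mean) / np.maximum(std, eps)
    return out


def compute_feature_stats(features: FeatureSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension mean/std of a (training) feature matrix."""
    return features.values.mean(axis=0), features.values.std(axis=0)


def extract_features(windows: WindowSet, kind: str, **kwargs) -> FeatureSet:
    """Dispatch by feature-set name: rms | wl | hist | mdwt | combined."""
    table = {
        "rms": feature_rms,
        "wl": feature_wl,
        "hist": feature_hist,
        "mdwt": feature_mdwt,
        "combined": feature_combined,
    }
    try:
        fn = table[kind]
    except KeyError:
        raise ValueError(f"unknown feature kind {kind!r}; expected one of {sorted(table)}") from None
    return fn(windows, **kwargs)
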