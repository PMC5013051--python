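"""Synthetic Ninapro-style sEMG recordings with known ground truth.

The generator emulates the structure of a guided-acquisition sEMG session:
a subject is prompted to perform each of ``n_movement_classes`` hand
movements for ``n_repetitions`` consecutive repetitions; each repetition
lasts ``movement_duration`` seconds and is followed by
``rest_duration`` seconds of rest.  The stimulus vector records the
*prompt* timing; because of human reaction times the subject's true
muscle activity lags the prompt by a per-repetition reaction lag, which
the ground-truth object records exactly.  Optional 50 Hz power-line
interference (plus harmonics) can be injected for the interference-removal
stage to act on.

Two electrode families are emulated:

``raw_2khz``
    The signal is a zero-mean Gaussian carrier band-passed to the typical
    sEMG band (20-450 Hz), amplitude-modulated per channel by the class
    activation pattern.
``rectified_100hz``
    The moving-RMS envelope of the same kind of modulated carrier,
    emulating electrodes that emit a nonnegative rectified envelope.

Class identity is carried by a per-class, per-channel gain pattern
(:class:`SignatureMatrix`); the ``separation`` scalar controls how far
class gain vectors lie apart, i.e. the difficulty of the downstream
classification problem.  Separation 0 removes all class information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .types import ELECTRODE_MODELS, Recording

__all__ = [
    "ProtocolSpec",
    "SignatureMatrix",
    "NoiseSettings",
    "GroundTruth",
    "make_class_signatures",
    "generate_recording",
]


@dataclass
class ProtocolSpec:
    """Acquisition protocol: what the subject was asked to do.

    Defaults follow the guided protocol of the emulated database: ~50
    movements, 5 s movement / 3 s rest repetitions, 10 repetitions with
    10 rectified electrodes at 100 Hz, or 6 repetitions with 12 raw
    electrodes at 2 kHz.
    """

    n_movement_classes: int = 50
    n_repetitions: int = 10
    movement_duration: float = 5.0
    rest_duration: float = 3.0
    sampling_rate: float = 100.0
    n_channels: int = 10
    electrode_model: str = "rectified_100hz"

    def __post_init__(self) -> None:
        if self.n_movement_classes < 1:
            raise ValueError("n_movement_classes must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.movement_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("durations must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.electrode_model not in ELECTRODE_MODELS:
            raise ValueError(f"unknown electrode_model {self.electrode_model!r}")

    @property
    def n_classes(self) -> int:
        """Number of classification classes including rest (class 0)."""
        return self.n_movement_classes + 1

    @property
    def total_duration(self) -> float:
        """Scheduled session length in seconds (with a leading rest block)."""
        per_rep = self.movement_duration + self.rest_duration
        return self.rest_duration + self.n_movement_classes * self.n_repetitions * per_rep

    def schedule(self) -> list[tuple[int, int, float, float]]:
        """Nominal movement timeline.

        Returns a list of ``(class_id, repetition_id, t_on, t_off)`` in
        seconds, with repetitions of each movement consecutive, as in a
        guided acquisition.
        """
        out = []
        t = self.rest_duration
        for k in range(1, self.n_movement_classes + 1):
            for r in range(1, self.n_repetitions + 1):
                out.append((k, r, t, t + self.movement_duration))
                t += self.movement_duration + self.rest_duration
        return out


@dataclass
class SignatureMatrix:
    """Per-class, per-channel activation gains.

    ``gains`` has shape ``(n_movement_classes + 1, n_channels)``; row 0 is
    the rest class and holds the baseline level only.  Gains are expressed
    as multiples of the rest baseline, so ``separation`` directly controls
    the signal-to-baseline ratio of movement activity.
    """

    gains: np.ndarray
    separation: float
    baseline: float = 1.0

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.ndim != 2:
            raise ValueError("gains must be 2-D (classes x channels)")
        if np.any(self.gains < 0):
            raise ValueError("gains must be nonnegative")

    @property
    def n_movement_classes(self) -> int:
        return self.gains.shape[0] - 1

    @property
    def n_channels(self) -> int:
        return self.gains.shape[1]


@dataclass
class NoiseSettings:
    """Interference and reaction-lag settings for the generator.

    ``lag_range`` bounds the uniform per-repetition reaction lag in
    seconds (plausible human reaction times); ``powerline_amplitude`` is
    the 50 Hz interference amplitude in baseline units (0 disables it);
    harmonics decay as 1/h up to ``powerline_harmonics`` (or the Nyquist
    limit).  ``ramp_duration`` is the linear onset/offset amplitude ramp.
    """

    lag_range: tuple[float, float] = (0.1, 0.5)
    powerline_amplitude: float = 0.0
    powerline_base: float = 50.0
    powerline_harmonics: int | None = None
    ramp_duration: float = 0.1
    carrier_band: tuple[float, float] = (20.0, 450.0)
    rectify_window: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.lag_range
        if lo < 0 or hi < lo:
            raise ValueError("lag_range must satisfy 0 <= lo <= hi")
        if self.powerline_amplitude < 0:
            raise ValueError("powerline_amplitude must be >= 0")


@dataclass
class GroundTruth:
    """Exact activity boundaries of a generated recording.

    ``true_onsets``/``true_offsets`` are sample indices of the subject's
    actual (reaction-lagged) activity for each scheduled movement
    repetition, in schedule order; ``class_sequence`` / ``repetitions``
    give the class and repetition id of each entry; ``reaction_lags`` the
    per-repetition lags in seconds.
    """

    class_sequence: np.ndarray
    repetitions: np.ndarray
    true_onsets: np.ndarray
    true_offsets: np.ndarray
    reaction_lags: np.ndarray
    nominal_onsets: np.ndarray = field(default=None)  # type: ignore[assignment]
    nominal_offsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.true_onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.true_offsets <= self.true_onsets):
            raise ValueError("each onset must precede its offset")
        if np.any(self.reaction_lags < 0):
            raise ValueError("reaction lags must be >= 0")


def make_class_signatures(
    n_classes: int,
    n_channels: int,
    separation: float,
    seed: int,
    baseline: float = 1.0,
) -> SignatureMatrix:
    """Draw a per-class channel activation pattern.

    Each movement class gets an independent uniform(0, 1) pattern over
    channels; its gain row is ``baseline * (1 + separation * pattern)``,
    so pairwise distances between class rows scale linearly with
    ``separation`` and vanish at separation 0 (classifiers at chance).

    Parameters
    ----------
    n_classes:
        Number of movement classes (rest is added as row 0).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    patterns = rng.uniform(0.0, 1.0, size=(n_classes, n_channels))
    gains = np.vstack([np.ones(n_channels), 1.0 + separation * patterns]) * baseline
    return SignatureMatrix(gains=gains, separation=float(separation), baseline=float(baseline))


def _moving_rms(x: np.ndarray, size: int) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    return np.sqrt(np.maximum(uniform_filter1d(x * x, size=size, axis=0, mode="nearest"), 0.0))


def generate_recording(
    protocol: ProtocolSpec,
    signatures: SignatureMatrix,
    noise: NoiseSettings | None = None,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Simulate one acquisition session.

    Returns the :class:`~semgkit.types.Recording` (stimulus/repetition at
    *nominal* prompt timing, signal at *true*, lagged timing) together
    with the exact :class:`GroundTruth`.
    """
    if noise is None:
        noise = NoiseSettings()
    if signatures.n_movement_classes != protocol.n_movement_classes:
        raise ValueError(
            f"signatures have {signatures.n_movement_classes} movement classes, "
            f"protocol expects {protocol.n_movement_classes}"
        )
    if signatures.n_channels != protocol.n_channels:
        raise ValueError(
            f"signatures have {signatures.n_channels} channels, "
            f"protocol expects {protocol.n_channels}"
        )

    fs = protocol.sampling_rate
    n = int(round(protocol.total_duration * fs))
    n_ch = protocol.n_channels
    sched = protocol.schedule()
    rng = np.random.default_rng(seed)

    stimulus = np.zeros(n, dtype=int)
    repetition = np.zeros(n, dtype=int)
    lags = rng.uniform(noise.lag_range[0], noise.lag_range[1], size=len(sched))

    ramp_n = max(int(round(noise.ramp_duration * fs)), 1)
    base = signatures.baseline

    # Per-channel amplitude envelope: baseline at rest, class gain during
    # true (lagged) activity, linear ramps at the boundaries.
    envelope = np.full((n, n_ch), base)
    true_on = np.empty(len(sched), dtype=int)
    true_off = np.empty(len(sched), dtype=int)
    classes = np.empty(len(sched), dtype=int)
    reps = np.empty(len(sched), dtype=int)
    nom_on = np.empty(len(sched), dtype=int)
    nom_off = np.empty(len(sched), dtype=int)

    for i, (k, r, t_on, t_off) in enumerate(sched):
        s_nom, e_nom = int(round(t_on * fs)), int(round(t_off * fs))
        stimulus[s_nom:e_nom] = k
        repetition[s_nom:e_nom] = r
        lag_n = int(round(lags[i] * fs))
        s_true = min(s_nom + lag_n, n - 2)
        e_true = min(e_nom + lag_n, n - 1)
        gain = signatures.gains[k]
        seg = np.ones(e_true - s_true)
        up = min(ramp_n, len(seg))
        seg[:up] = np.linspace(0.0, 1.0, up + 1)[1:]
        down = min(ramp_n, len(seg))
        seg[len(seg) - down:] = np.minimum(seg[len(seg) - down:], np.linspace(1.0, 0.0, down + 1)[:-1])
        envelope[s_true:e_true] = base + seg[:, None] * (gain[None, :] - base)
        classes[i], reps[i] = k, r
        true_on[i], true_off[i] = s_true, e_true
        nom_on[i], nom_off[i] = s_nom, e_nom

    # Carrier generated per channel to bound peak memory on long sessions.
    emg = np.empty((n, n_ch))
    if protocol.electrode_model == "raw_2khz":
        lo, hi = noise.carrier_band
        hi = min(hi, 0.45 * fs)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        for c in range(n_ch):
            white = rng.standard_normal(n)
            carrier = sps.sosfiltfilt(sos, white)
            carrier /= max(carrier.std(), 1e-12)
            emg[:, c] = envelope[:, c] * carrier
    else:  # rectified_100hz: nonnegative moving-RMS envelope of the carrier
        size = max(int(round(noise.rectify_window * fs)), 2)
        for c in range(n_ch):
            white = rng.standard_normal(n)
            emg[:, c] = _moving_rms((envelope[:, c] * white)[:, None], size)[:, 0]

    if noise.powerline_amplitude > 0:
        nyq = fs / 2.0
        max_h = noise.powerline_harmonics
        t = np.arange(n) / fs
        h = 1
        while True:
            f = noise.powerline_base * h
            if f >= nyq or (max_h is not None and h > max_h):
                break
            phases = rng.uniform(0, 2 * np.pi, size=n_ch)
            emg += (noise.powerline_amplitude / h) * np.sin(
                2 * np.pi * f * t[:, None] + phases[None, :]
            )
            h += 1

    recording = Recording(
        emg=emg,
        stimulus=stimulus,
        repetition=repetition,
        sampling_rate=fs,
        electrode_model=protocol.electrode_model,
        subject_meta={"synthetic": True, "seed": int(seed), "separation": signatures.separation},
    )
    truth = GroundTruth(
        class_sequence=classes,
        repetitions=reps,
        true_onsets=true_on,
        true_offsets=true_off,
        reaction_lags=lags,
        nominal_onsets=nom_on,
        nominal_offsets=nom_off,
    )
    return recording, truth
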