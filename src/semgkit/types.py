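"""Core containers shared across the pipeline.

A :class:`Recording` is the universal currency of the pipeline: a
multichannel sEMG matrix together with the per-sample stimulus (movement
class, 0 = rest) and repetition vectors plus acquisition metadata.  A
:class:`WindowSet` is a batch of fixed-length labelled segments cut from a
recording; it is stored as a dense array rather than one object per window
so that feature extraction and training operate on contiguous memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Supported electrode families.  ``rectified_100hz`` emulates electrodes
#: that deliver an amplified, RMS-rectified envelope at 100 Hz;
#: ``raw_2khz`` emulates wireless electrodes delivering the raw,
#: oscillating signal at 2 kHz.
ELECTRODE_MODELS = ("rectified_100hz", "raw_2khz")


@dataclass
class Recording:
    """Multichannel sEMG recording with per-sample labels.

    Attributes
    ----------
    emg:
        ``(n_samples, n_channels)`` float matrix.
    stimulus:
        ``(n_samples,)`` int vector of movement class ids, 0 for rest.
    repetition:
        ``(n_samples,)`` int vector of repetition ids, 0 for rest.
    sampling_rate:
        Sampling rate in Hz.
    electrode_model:
        One of :data:`ELECTRODE_MODELS`.
    subject_meta:
        Free-form subject / provenance key-values.
    extras:
        Opaque additional streams (e.g. glove, inclinometer); carried
        through I/O, never interpreted.
    """

    emg: np.ndarray
    stimulus: np.ndarray
    repetition: np.ndarray
    sampling_rate: float
    electrode_model: str = "raw_2khz"
    subject_meta: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.stimulus = np.asarray(self.stimulus).astype(int).ravel()
        self.repetition = np.asarray(self.repetition).astype(int).ravel()
        self.sampling_rate = float(self.sampling_rate)

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def with_labels(self, stimulus: np.ndarray, repetition: np.ndarray) -> "Recording":
        """Copy of the recording with replaced label vectors."""
        return replace(self, stimulus=np.asarray(stimulus), repetition=np.asarray(repetition))

    def with_emg(self, emg: np.ndarray) -> "Recording":
        """Copy of the recording with a replaced signal matrix."""
        return replace(self, emg=np.asarray(emg))


@dataclass
class WindowSet:
    """Batch of fixed-duration labelled windows.

    ``samples`` has shape ``(n_windows, window_length, n_channels)``;
    ``labels``/``repetitions`` hold one class / repetition id per window,
    and ``t_start`` the window start time in seconds of the source
    recording.
    """

    samples: np.ndarray
    labels: np.ndarray
    repetitions: np.ndarray
    t_start: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels).astype(int).ravel()
        self.repetitions = np.asarray(self.repetitions).astype(int).ravel()
        self.t_start = np.asarray(self.t_start, dtype=float).ravel()

    @property
    def n_windows(self) -> int:
        return self.samples.shape[0]

    @property
    def window_length(self) -> int:
        return self.samples.shape[1]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[2]

    def __len__(self) -> int:
        return self.n_windows

    def select(self, index: np.ndarray) -> "WindowSet":
        """Subset (by boolean mask or integer index array)."""
        index = np.asarray(index)
        return WindowSet(
            samples=self.samples[index],
            labels=self.labels[index],
            repetitions=self.repetitions[index],
            t_start=self.t_start[index],
            sampling_rate=self.sampling_rate,
        )

    def with_samples(self, samples: np.ndarray) -> "WindowSet":
        """Copy with replaced sample tensor (labels untouched)."""
        return WindowSet(
            samples=np.asarray(samples),
            labels=self.labels.copy(),
            repetitions=self.repetitions.copy(),
            t_start=self.t_start.copy(),
            sampling_rate=self.sampling_rate,
        )


def concatenate_window_sets(sets: list[WindowSet]) -> WindowSet:
    """Stack several window sets (equal window length / channel count)."""
    if not sets:
        raise ValueError("need at least one window set")
    rates = {ws.sampling_rate for ws in sets}
    if len(rates) != 1:
        raise ValueError(f"mixed sampling rates: {sorted(rates)}")
    return WindowSet(
        samples=np.concatenate([ws.samples for ws in sets], axis=0),
        labels=np.concatenate([ws.labels for ws in sets]),
        repetitions=np.concatenate([ws.repetitions for ws in sets]),
        t_start=np.concatenate([ws.t_start for ws in sets]),
        sampling_rate=sets[0].sampling_rate,
    )
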