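"""Windowing and repetition-wise train/test splitting.

Recordings are cut into fixed-duration, densely strided windows; whole
movement repetitions (never individual windows) are assigned to train or
test, which prevents temporal leakage between the two sets.  The
canonical held-out repetitions are {2, 5, 7} for 10-repetition protocols
and {2, 5} for 6-repetition protocols (approximately one third of the
movement repetitions in each case).
"""

from __future__ import annotations

import logging

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import Recording, WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "extract_windows",
    "split_by_repetition",
    "balance_classes",
    "default_test_repetitions",
]

#: Canonical held-out repetitions per protocol size.
_DEFAULT_TEST_REPS = {10: (2, 5, 7), 6: (2, 5)}


def _majority(rows: np.ndarray) -> np.ndarray:
    """Row-wise majority vote over small nonnegative ints (ties -> smallest id)."""
    n, _ = rows.shape
    vmax = int(rows.max()) + 1 if rows.size else 1
    offsets = np.arange(n)[:, None] * vmax
    counts = np.bincount((rows + offsets).ravel(), minlength=n * vmax).reshape(n, vmax)
    return counts.argmax(axis=1)


def _effective_repetition(stimulus: np.ndarray, repetition: np.ndarray) -> np.ndarray:
    """Repetition context for every sample.

    Rest samples inherit the repetition id of the preceding movement
    (leading rest inherits the following one), so rest windows can be
    assigned to the split of their surrounding repetition.
    """
    rep = np.asarray(repetition).copy()
    active = rep > 0
    if not active.any():
        return rep
    idx = np.where(active, np.arange(rep.size), -1)
    last = np.maximum.accumulate(idx)
    filled = np.where(last >= 0, rep[np.maximum(last, 0)], 0)
    # leading rest: take the first active repetition id
    first_active = np.argmax(active)
    filled[:first_active] = rep[first_active]
    return filled


def extract_windows(recording: Recording, window: float, stride: float) -> WindowSet:
    """Cut the recording into labelled windows.

    ``window`` and ``stride`` are in seconds.  Windows tile the recording
    at the given stride; each is labelled by the majority stimulus id
    among its samples (ties go to the smaller id), and carries the
    majority surrounding repetition id, so boundary windows are kept
    rather than discarded.  The window count is
    ``floor((L - w) / s) + 1``.
    """
    fs = recording.sampling_rate
    w = int(round(window * fs))
    s = max(int(round(stride * fs)), 1)
    if w < 2:
        raise ValueError(f"window of {window}s is shorter than 2 samples at {fs} Hz")
    L = recording.n_samples
    if w > L:
        logger.warning("window (%d samples) longer than recording (%d); empty window set", w, L)
        return WindowSet(
            samples=np.empty((0, w, recording.n_channels)),
            labels=np.empty(0, dtype=int),
            repetitions=np.empty(0, dtype=int),
            t_start=np.empty(0),
            sampling_rate=fs,
        )

    samples = sliding_window_view(recording.emg, w, axis=0)[::s]  # (n, C, w)
    samples = np.ascontiguousarray(samples.transpose(0, 2, 1))  # (n, w, C)
    stim_win = sliding_window_view(recording.stimulus, w)[::s]
    labels = _majority(stim_win)

    eff_rep = _effective_repetition(recording.stimulus, recording.repetition)
    rep_win = sliding_window_view(eff_rep, w)[::s]
    reps = _majority(rep_win)

    n = samples.shape[0]
    t_start = np.arange(n) * s / fs
    return WindowSet(
        samples=samples,
        labels=labels,
        repetitions=reps,
        t_start=t_start,
        sampling_rate=fs,
    )


def default_test_repetitions(n_repetitions: int) -> tuple[int, ...]:
    """Canonical held-out repetitions ({2,5,7} for 10, {2,5} for 6)."""
    try:
        return _DEFAULT_TEST_REPS[n_repetitions]
    except KeyError:
        raise ValueError(
            f"no canonical test repetitions for n_repetitions={n_repetitions}; "
            "pass an explicit test_reps list"
        ) from None


def split_by_repetition(
    windows: WindowSet,
    n_repetitions: int,
    test_reps: list[int] | tuple[int, ...] | None = None,
) -> tuple[WindowSet, WindowSet]:
    """Repetition-wise train/test split.

    Returns ``(train, test)``; a window is in test iff its repetition id
    is in ``test_reps`` (default: canonical set for the protocol size).
    Rest windows follow their surrounding repetition.  The two sets are
    disjoint and exhaustive.
    """
    if test_reps is None:
        test_reps = default_test_repetitions(n_repetitions)
    test_reps = set(int(r) for r in test_reps)
    in_test = np.isin(windows.repetitions, sorted(test_reps))
    return windows.select(~in_test), windows.select(in_test)


def balance_classes(
    windows: WindowSet,
    strategy: str = "median_subsample",
    seed: int = 0,
    expected_classes: list[int] | None = None,
) -> WindowSet:
    """Subsample over-represented classes.

    The default strategy subsamples every class (including rest, which
    otherwise dominates the window count) down to the median movement-
    class window count; classes at or below the median are kept whole.
    Deterministic for a fixed seed.
    """
    if strategy != "median_subsample":
        raise ValueError(f"unknown balancing strategy {strategy!r}")
    labels = windows.labels
    present, counts = np.unique(labels, return_counts=True)
    if expected_classes is not None:
        missing = sorted(set(int(c) for c in expected_classes) - set(present.tolist()))
        if missing:
            raise ValueError(f"no windows for class(es) {missing}")
    movement_counts = counts[present > 0]
    if movement_counts.size == 0:
        raise ValueError("no movement windows to balance against")
    target = int(np.median(movement_counts))
    rng = np.random.default_rng(seed)
    keep = np.zeros(windows.n_windows, dtype=bool)
    for cls, cnt in zip(present, counts):
        idx = np.flatnonzero(labels == cls)
        if cnt > target:
            idx = rng.choice(idx, size=target, replace=False)
        keep[idx] = True
    return windows.select(np.flatnonzero(keep))
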