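"""Reading and writing Ninapro-style recordings.

Two on-disk dialects are supported:

``mat_container``
    The distribution format of the public sEMG benchmark databases: a MAT
    container with ``emg`` (samples x channels), ``stimulus`` and
    ``repetition`` column vectors and a scalar ``frequency``.  When the
    offline-relabelled variants ``restimulus`` / ``rerepetition`` are
    present they are preferred (the relabelled vectors are authoritative
    for analysis); which pair was used is recorded in
    ``subject_meta["label_source"]``.

``columnar_text``
    A plain-text dialect for small fixtures: ``#``-prefixed header lines
    carrying a JSON metadata object, then one tab-separated row per
    sample: ``stimulus  repetition  emg_ch0 ... emg_chN``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io

from .errors import FormatError, IntegrityError
from .types import ELECTRODE_MODELS, Recording

__all__ = ["load_recording", "save_recording", "validate_recording", "ValidationReport"]

# Accepted field aliases across database releases.  Documented aliases
# only; anything else is a format error.
_EMG_KEYS = ("emg",)
_STIM_KEYS = ("restimulus", "stimulus", "glove_stimulus")
_REP_KEYS = ("rerepetition", "repetition")
_RATE_KEYS = ("frequency", "fs", "sampling_rate")
_RELABELED = {"restimulus", "rerepetition"}

_PASSTHROUGH_KEYS = ("glove", "inclin", "force", "acc")


def _first_key(d: dict, keys: tuple[str, ...]):
    for k in keys:
        if k in d:
            return k
    return None


def save_recording(recording: Recording, path, format: str | None = None) -> None:
    """Write a recording; format inferred from the suffix when omitted
    (``.mat`` -> MAT container, anything else -> columnar text)."""
    path = Path(path)
    if recording.n_samples == 0:
        raise ValueError("empty recordings are not representable")
    if format is None:
        format = "mat_container" if path.suffix.lower() == ".mat" else "columnar_text"
    if format == "mat_container":
        payload = {
            "emg": recording.emg,
            "stimulus": recording.stimulus.reshape(-1, 1),
            "repetition": recording.repetition.reshape(-1, 1),
            "frequency": float(recording.sampling_rate),
            "electrode_model": recording.electrode_model,
        }
        if recording.subject_meta:
            payload["subject_meta"] = json.dumps(recording.subject_meta)
        for key, value in recording.extras.items():
            payload[key] = value
        scipy.io.savemat(str(path), payload, do_compression=True)
    elif format == "columnar_text":
        meta = {
            "sampling_rate": recording.sampling_rate,
            "electrode_model": recording.electrode_model,
            "n_channels": recording.n_channels,
            "subject_meta": recording.subject_meta,
        }
        body = np.column_stack(
            [recording.stimulus, recording.repetition, recording.emg]
        )
        header = "semgkit-recording " + json.dumps(meta)
        np.savetxt(path, body, header=header, delimiter="\t", fmt="%.10g")
    else:
        raise ValueError(f"unknown format {format!r}")


def _load_mat(path: Path) -> Recording:
    try:
        raw = scipy.io.loadmat(str(path), squeeze_me=True)
    except NotImplementedError as exc:  # v7.3 container
        raise FormatError(
            f"{path}: MAT v7.3 containers are not supported; re-save as v7 or earlier"
        ) from exc
    data = {k: v for k, v in raw.items() if not k.startswith("__")}

    emg_key = _first_key(data, _EMG_KEYS)
    if emg_key is None:
        raise FormatError(f"{path}: missing required field 'emg'")
    stim_key = _first_key(data, _STIM_KEYS)
    if stim_key is None:
        raise FormatError(f"{path}: missing required field 'stimulus' (or 'restimulus')")
    rep_key = _first_key(data, _REP_KEYS)
    if rep_key is None:
        raise FormatError(f"{path}: missing required field 'repetition' (or 'rerepetition')")
    rate_key = _first_key(data, _RATE_KEYS)
    if rate_key is None:
        raise FormatError(f"{path}: missing required field 'frequency'")

    emg = np.atleast_2d(np.asarray(data[emg_key], dtype=float))
    stimulus = np.asarray(data[stim_key]).ravel()
    repetition = np.asarray(data[rep_key]).ravel()
    rate = float(np.asarray(data[rate_key]).ravel()[0])

    if emg.shape[0] != stimulus.size or emg.shape[0] != repetition.size:
        raise IntegrityError(
            f"{path}: length mismatch (emg {emg.shape[0]}, "
            f"stimulus {stimulus.size}, repetition {repetition.size})"
        )

    model = data.get("electrode_model")
    if isinstance(model, np.ndarray):
        model = str(model.ravel()[0]) if model.size else None
    if model not in ELECTRODE_MODELS:
        model = "rectified_100hz" if rate <= 200 else "raw_2khz"

    meta = {}
    if "subject_meta" in data:
        try:
            meta = json.loads(str(data["subject_meta"]))
        except (json.JSONDecodeError, TypeError):
            meta = {}
    for k in ("subject", "exercise"):
        if k in data and np.asarray(data[k]).size == 1:
            meta.setdefault(k, int(np.asarray(data[k]).ravel()[0]))
    meta["label_source"] = "relabeled" if stim_key in _RELABELED else "original"

    extras = {
        k: v
        for k, v in data.items()
        if any(k.startswith(p) for p in _PASSTHROUGH_KEYS)
    }
    return Recording(
        emg=emg,
        stimulus=stimulus,
        repetition=repetition,
        sampling_rate=rate,
        electrode_model=model,
        subject_meta=meta,
        extras=extras,
    )


def _load_text(path: Path) -> Recording:
    meta = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line.lstrip("# ").strip()
            if stripped.startswith("semgkit-recording "):
                meta = json.loads(stripped[len("semgkit-recording "):])
    if meta is None:
        raise FormatError(f"{path}: missing 'semgkit-recording' metadata header")
    body = np.loadtxt(path, ndmin=2)
    if body.shape[1] < 3:
        raise FormatError(f"{path}: expected >= 3 columns (stimulus, repetition, emg...)")
    n_ch = int(meta.get("n_channels", body.shape[1] - 2))
    if body.shape[1] - 2 != n_ch:
        raise IntegrityError(
            f"{path}: header declares {n_ch} channels, file has {body.shape[1] - 2}"
        )
    return Recording(
        emg=body[:, 2:],
        stimulus=body[:, 0],
        repetition=body[:, 1],
        sampling_rate=float(meta["sampling_rate"]),
        electrode_model=meta.get("electrode_model", "raw_2khz"),
        subject_meta=dict(meta.get("subject_meta", {})),
    )


def load_recording(path) -> Recording:
    """Load a recording from a MAT container or columnar-text file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".mat":
        return _load_mat(path)
    return _load_text(path)


@dataclass
class ValidationReport:
    """Per-invariant pass/fail results for a recording."""

    checks: list[tuple[str, bool, str]]

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[str]:
        return [name for name, ok, _ in self.checks if not ok]

    def __str__(self) -> str:
        lines = [
            f"[{'ok' if ok else 'FAIL'}] {name}: {detail}" for name, ok, detail in self.checks
        ]
        return "\n".join(lines)


def validate_recording(recording: Recording) -> ValidationReport:
    """Check the recording invariants; reports, never raises."""
    checks: list[tuple[str, bool, str]] = []
    n = recording.emg.shape[0]

    ok = recording.emg.ndim == 2 and recording.emg.shape[1] >= 1
    checks.append(("emg_matrix", ok, f"shape {recording.emg.shape}"))

    ok = recording.stimulus.size == n and recording.repetition.size == n
    checks.append(
        (
            "length_match",
            ok,
            f"emg {n}, stimulus {recording.stimulus.size}, repetition {recording.repetition.size}",
        )
    )

    ok = bool(recording.stimulus.size == 0 or recording.stimulus.min() >= 0)
    checks.append(("label_range", ok, f"min stimulus id {recording.stimulus.min() if recording.stimulus.size else 'n/a'}"))

    ok = bool(recording.repetition.size == 0 or recording.repetition.min() >= 0)
    checks.append(("repetition_range", ok, "repetition ids nonnegative"))

    ok = recording.sampling_rate > 0
    checks.append(("sampling_rate", ok, f"{recording.sampling_rate} Hz"))

    ok = bool(np.isfinite(recording.emg).all())
    checks.append(("finite_signal", ok, "all samples finite"))

    ok = recording.electrode_model in ELECTRODE_MODELS
    checks.append(("electrode_model", ok, recording.electrode_model))

    return ValidationReport(checks=checks)
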