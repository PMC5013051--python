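"""Configuration-driven experiments: simulate/load -> preprocess ->
window -> split -> classify -> score.

An experiment config (YAML/JSON or a plain dict) has exactly one
classification arm — ``cnn`` (the convolutional network on low-passed
envelope windows) or ``baseline`` (a classical classifier on window
features) — plus a data source (``synthetic`` generator block or
``data.paths`` of recording files), and optional ``preprocess``,
``windows``, ``split`` and ``balance`` blocks.  A single global seed is
fanned out deterministically to every stochastic stage, so a rerun of
the same config reproduces the same report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import baselines, cnn, evaluation, io, preprocessing, segmentation, synthetic
from .features import compute_feature_stats, extract_features
from .types import Recording, WindowSet, concatenate_window_sets

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

_STAGE_NAMES = (
    "signatures",
    "recording",
    "balance",
    "augment",
    "training",
    "baseline",
    "test_balance",
)


def _fan_out_seeds(seed: int) -> dict[str, int]:
    """Derive one sub-seed per stochastic stage from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_NAMES, children)
    }


@dataclass
class ExperimentConfig:
    """Validated experiment description."""

    seed: int = 0
    output_dir: str | None = None
    arm: str = "cnn"
    synthetic: dict | None = None
    data: dict | None = None
    preprocess: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    balance: dict = field(default_factory=dict)
    cnn: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        has_cnn = "cnn" in raw
        has_baseline = "baseline" in raw
        if has_cnn and has_baseline:
            raise ValueError("config enables both classification arms; keep exactly one")
        arm = "baseline" if has_baseline else "cnn"
        if (raw.get("synthetic") is None) == (raw.get("data") is None):
            raise ValueError("config needs exactly one data source: 'synthetic' or 'data'")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known - {"arm"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir"),
            arm=arm,
            synthetic=raw.get("synthetic"),
            data=raw.get("data"),
            preprocess=dict(raw.get("preprocess", {})),
            windows=dict(raw.get("windows", {})),
            split=dict(raw.get("split", {})),
            balance=dict(raw.get("balance", {})),
            cnn=dict(raw.get("cnn", {})),
            baseline=dict(raw.get("baseline", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "preprocess": self.preprocess,
            "windows": self.windows,
            "split": self.split,
            "balance": self.balance,
        }
        if self.synthetic is not None:
            out["synthetic"] = self.synthetic
        if self.data is not None:
            out["data"] = self.data
        if self.arm == "cnn":
            out["cnn"] = self.cnn
        else:
            out["baseline"] = self.baseline
        return out


@dataclass
class ExperimentResult:
    """Scores and artifacts of one experiment run."""

    arm: str
    report: evaluation.EvaluationReport
    balanced_report: evaluation.EvaluationReport
    segment_majority_accuracy: float
    n_train_windows: int
    n_test_windows: int
    history: list[float] | None
    log: list[str]
    seeds: dict[str, int]


def _obtain_recording(cfg: ExperimentConfig, seeds: dict[str, int], log: list[str]):
    if cfg.synthetic is not None:
        syn = dict(cfg.synthetic)
        separation = float(syn.pop("separation", 5.0))
        noise_kwargs = {}
        for key in ("lag_range", "powerline_amplitude", "powerline_base",
                    "powerline_harmonics", "ramp_duration"):
            if key in syn:
                noise_kwargs[key] = syn.pop(key)
        if "lag_range" in noise_kwargs:
            noise_kwargs["lag_range"] = tuple(noise_kwargs["lag_range"])
        protocol = synthetic.ProtocolSpec(**syn)
        signatures = synthetic.make_class_signatures(
            protocol.n_movement_classes,
            protocol.n_channels,
            separation,
            seed=seeds["signatures"],
        )
        noise = synthetic.NoiseSettings(**noise_kwargs)
        recording, _truth = synthetic.generate_recording(
            protocol, signatures, noise, seed=seeds["recording"]
        )
        log.append(
            f"synthetic: {protocol.n_movement_classes} movements x "
            f"{protocol.n_repetitions} reps, {protocol.n_channels} ch @ "
            f"{protocol.sampling_rate} Hz ({protocol.electrode_model}), "
            f"separation {separation}"
        )
        return [recording], protocol.n_repetitions
    paths = cfg.data.get("paths", [])
    if not paths:
        raise ValueError("data source block needs a non-empty 'paths' list")
    recordings = [io.load_recording(p) for p in paths]
    n_reps = int(cfg.data.get("n_repetitions", int(max(r.repetition.max() for r in recordings))))
    log.append(f"loaded {len(recordings)} recording(s); n_repetitions={n_reps}")
    return recordings, n_reps


def _windows_for_arm(
    cfg: ExperimentConfig,
    recordings: list[Recording],
    log: list[str],
) -> WindowSet:
    pp = preprocessing.PreprocessConfig(**cfg.preprocess)
    if cfg.arm == "cnn":
        length_ms = float(cfg.windows.get("cnn_ms", 150.0))
    else:
        length_ms = float(cfg.windows.get("classical_ms", 200.0))
    stride_ms = float(cfg.windows.get("stride_ms", 10.0))
    sets = []
    for rec in recordings:
        if cfg.arm == "cnn":
            prepped, stage_log = preprocessing.preprocess_for_cnn(rec, pp)
        else:
            prepped, stage_log = preprocessing.preprocess_for_classical(rec, pp)
        log.extend(stage_log)
        sets.append(
            segmentation.extract_windows(prepped, length_ms / 1000.0, stride_ms / 1000.0)
        )
    windows = concatenate_window_sets(sets)
    log.append(
        f"windows: {windows.n_windows} x {windows.window_length} samples x "
        f"{windows.n_channels} ch ({length_ms:g} ms / stride {stride_ms:g} ms)"
    )
    return windows


def _segment_majority_accuracy(
    pred_labels: np.ndarray, test: WindowSet
) -> float:
    """Majority-vote accuracy over movement instances (class, repetition)."""
    correct, total = 0, 0
    for key in set(zip(test.labels.tolist(), test.repetitions.tolist())):
        cls, rep = key
        if cls == 0:
            continue
        mask = (test.labels == cls) & (test.repetitions == rep)
        votes = np.bincount(pred_labels[mask])
        total += 1
        if votes.argmax() == cls:
            correct += 1
    return 100.0 * correct / total if total else float("nan")


def run_experiment(config: ExperimentConfig | dict) -> ExperimentResult:
    """Execute one experiment end to end; see module docstring."""
    cfg = config if isinstance(config, ExperimentConfig) else ExperimentConfig.from_dict(config)
    seeds = _fan_out_seeds(cfg.seed)
    log: list[str] = [f"seed fan-out: {seeds}"]

    recordings, n_reps = _obtain_recording(cfg, seeds, log)
    windows = _windows_for_arm(cfg, recordings, log)

    test_reps = cfg.split.get("test_reps")
    train, test = segmentation.split_by_repetition(windows, n_reps, test_reps)
    log.append(f"split: {train.n_windows} train / {test.n_windows} test windows")
    train = segmentation.balance_classes(
        train, cfg.balance.get("strategy", "median_subsample"), seed=seeds["balance"]
    )
    log.append(f"balance: {train.n_windows} train windows after class balancing")

    history = None
    if cfg.arm == "cnn":
        norm_mode = cfg.cnn.get("normalization", "none")
        stats = (
            preprocessing.compute_window_stats(train) if norm_mode == "train_stats" else None
        )
        train_n = preprocessing.normalize_windows(train, norm_mode, stats)
        test_n = preprocessing.normalize_windows(test, norm_mode, stats)

        aug_cfg = cnn.AugmentationConfig(
            seed=seeds["augment"], **cfg.cnn.get("augmentation", {})
        )
        train_aug = cnn.augment_gaussian(train_n, aug_cfg)
        log.append(
            f"augment: {train_n.n_windows} -> {train_aug.n_windows} windows "
            f"(snr {aug_cfg.snr} {aug_cfg.snr_mode})"
        )

        n_classes = int(max(windows.labels.max(), 1)) + 1
        spec = cnn.build_network((train.window_length, train.n_channels), n_classes)
        log.append(f"network: k4={spec.k4}, {spec.parameter_count()} parameters")
        tr_cfg = cnn.TrainingConfig(seed=seeds["training"], **cfg.cnn.get("training", {}))
        model, history = cnn.train_cnn(spec, train_aug, tr_cfg)
        scores = cnn.predict_cnn(model, test_n)
        pred_labels = scores.argmax(axis=1)
        k_list = (1, 5) if n_classes > 5 else (1,)
        report = evaluation.score(scores, test_n.labels, k_list=k_list, n_classes=n_classes)
        test_bal = segmentation.balance_classes(test_n, seed=seeds["test_balance"])
        bal_scores = cnn.predict_cnn(model, test_bal)
        balanced_report = evaluation.score(
            bal_scores, test_bal.labels, k_list=k_list, n_classes=n_classes
        )
        test_for_majority = test_n
    else:
        kind = cfg.baseline.get("kind", "random_forest")
        feature_kind = cfg.baseline.get("features", "combined")
        hp = dict(cfg.baseline.get("hyperparameters", {}))
        n_classes = int(max(windows.labels.max(), 1)) + 1

        if feature_kind == "combined":
            raw_train = extract_features(train, "combined", train_stats=None)
            stats = compute_feature_stats(raw_train)
            feats_train = extract_features(train, "combined", train_stats=stats)
            feats_test = extract_features(test, "combined", train_stats=stats)
        else:
            feats_train = extract_features(train, feature_kind)
            feats_test = extract_features(test, feature_kind)

        if kind == "svm" and not hp:
            val_rep = int(np.unique(feats_train.repetitions)[0])
            hp = baselines.select_svm_hyperparameters(
                feats_train, val_rep, seed=seeds["baseline"]
            )
            log.append(f"svm grid selection on repetition {val_rep}: {hp}")
        spec_b = baselines.BaselineModelSpec(kind, hp, seed=seeds["baseline"])
        model_b = baselines.train_baseline(feats_train, spec_b)
        pred_labels, proba = baselines.predict_baseline(model_b, feats_test)
        if proba is not None:
            # align probability columns with contiguous class ids
            classes = np.asarray(model_b.estimator.classes_, dtype=int)
            full = np.zeros((proba.shape[0], n_classes))
            full[:, classes] = proba
            k_list = (1, 5) if n_classes > 5 else (1,)
            report = evaluation.score(full, feats_test.labels, k_list=k_list, n_classes=n_classes)
        else:
            report = evaluation.score(pred_labels, feats_test.labels, k_list=(1,), n_classes=n_classes)

        test_bal = segmentation.balance_classes(test, seed=seeds["test_balance"])
        if feature_kind == "combined":
            feats_bal = extract_features(test_bal, "combined", train_stats=stats)
        else:
            feats_bal = extract_features(test_bal, feature_kind)
        bal_pred, bal_proba = baselines.predict_baseline(model_b, feats_bal)
        if bal_proba is not None:
            classes = np.asarray(model_b.estimator.classes_, dtype=int)
            full = np.zeros((bal_proba.shape[0], n_classes))
            full[:, classes] = bal_proba
            balanced_report = evaluation.score(
                full, feats_bal.labels, k_list=(1, 5) if n_classes > 5 else (1,), n_classes=n_classes
            )
        else:
            balanced_report = evaluation.score(
                bal_pred, feats_bal.labels, k_list=(1,), n_classes=n_classes
            )
        test_for_majority = test
        pred_labels = np.asarray(pred_labels)

    seg_acc = _segment_majority_accuracy(np.asarray(pred_labels), test_for_majority)
    log.append(
        f"test accuracy: {report.overall_accuracy:.2f}% "
        f"(balanced {balanced_report.overall_accuracy:.2f}%, "
        f"segment-majority {seg_acc:.2f}%)"
    )

    result = ExperimentResult(
        arm=cfg.arm,
        report=report,
        balanced_report=balanced_report,
        segment_majority_accuracy=seg_acc,
        n_train_windows=train.n_windows,
        n_test_windows=test.n_windows,
        history=history,
        log=log,
        seeds=seeds,
    )
    if cfg.output_dir:
        _write_artifacts(cfg, result)
    return result


def _write_artifacts(cfg: ExperimentConfig, result: ExperimentResult) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        fh.write(result.report.to_json())
    with open(out / "balanced_report.json", "w") as fh:
        fh.write(result.balanced_report.to_json())
    with open(out / "log.txt", "w") as fh:
        fh.write("\n".join(result.log) + "\n")
    if result.history is not None:
        with open(out / "training_history.tsv", "w") as fh:
            fh.write("epoch\tmean_loss\n")
            for i, loss in enumerate(result.history, start=1):
                fh.write(f"{i}\t{loss:.8f}\n")
    summary = {
        "arm": result.arm,
        "overall_accuracy": result.report.overall_accuracy,
        "balanced_accuracy": result.balanced_report.overall_accuracy,
        "segment_majority_accuracy": result.segment_majority_accuracy,
        "seeds": result.seeds,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
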