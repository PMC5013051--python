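"""Reference classifiers over classical features.

Random forest, RBF-kernel support-vector machine (one-vs-one multiclass)
and k-nearest-neighbors, as commonly applied to windowed sEMG features.
These are thin, seeded wrappers around scikit-learn estimators; each
trained model remembers the feature layout it was fitted on and refuses
to predict on a different one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import LayoutMismatchError
from .features import FeatureSet

__all__ = [
    "BaselineModelSpec",
    "BaselineModel",
    "train_baseline",
    "predict_baseline",
    "select_svm_hyperparameters",
]

_KINDS = ("random_forest", "svm", "knn")

# Defaults follow common practice on this problem family; the source
# studies cite the classifiers without hyperparameters, so these are
# explicitly non-authoritative and overridable per experiment.
_DEFAULT_HP = {
    "random_forest": {"n_trees": 100},
    "svm": {"C": 10.0, "gamma": "scale"},
    "knn": {"k": 1},
}


@dataclass
class BaselineModelSpec:
    """Classifier kind + hyperparameters + seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}; expected one of {_KINDS}")
        merged = dict(_DEFAULT_HP[self.kind])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


@dataclass
class BaselineModel:
    """Trained handle: estimator + the feature layout it was fitted on."""

    spec: BaselineModelSpec
    estimator: object
    layout: list[str]


def _build_estimator(spec: BaselineModelSpec):
    hp = spec.hyperparameters
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp["n_trees"]),
            random_state=int(spec.seed),
            n_jobs=1,
        )
    if spec.kind == "svm":
        # SVC is one-vs-one internally for multiclass problems.
        return SVC(C=float(hp["C"]), gamma=hp["gamma"], kernel="rbf", random_state=int(spec.seed))
    return KNeighborsClassifier(n_neighbors=int(hp["k"]))


def train_baseline(features: FeatureSet, spec: BaselineModelSpec) -> BaselineModel:
    """Fit a baseline classifier; deterministic for a fixed seed."""
    classes = np.unique(features.labels)
    if classes.size < 2:
        raise ValueError(f"training set contains a single class ({classes.tolist()})")
    est = _build_estimator(spec)
    est.fit(features.values, features.labels)
    return BaselineModel(spec=spec, estimator=est, layout=list(features.names))


def predict_baseline(
    model: BaselineModel, features: FeatureSet
) -> tuple[np.ndarray, np.ndarray | None]:
    """Predict labels (+ per-class scores when the kind provides them).

    Returns ``(labels, scores)``; ``scores`` is an ``(n, n_classes)``
    matrix aligned with ``model.estimator.classes_`` for kinds exposing
    class probabilities (random forest, k-NN) and ``None`` for the SVM.
    """
    if list(features.names) != model.layout:
        raise LayoutMismatchError(
            f"feature layout mismatch: model trained on {len(model.layout)} dims "
            f"starting {model.layout[:3]}, got {len(features.names)} dims "
            f"starting {features.names[:3]}"
        )
    if features.n_windows == 0:
        return np.empty(0, dtype=int), None
    labels = model.estimator.predict(features.values)
    scores = None
    if hasattr(model.estimator, "predict_proba") and model.spec.kind != "svm":
        scores = model.estimator.predict_proba(features.values)
    return np.asarray(labels), scores


def select_svm_hyperparameters(
    train: FeatureSet,
    validation_rep: int,
    c_grid: tuple[float, ...] = (1.0, 10.0, 100.0),
    gamma_grid: tuple = ("scale", 0.01, 0.001),
    seed: int = 0,
) -> dict:
    """Small C/gamma grid search on a held-out training repetition."""
    val_mask = train.repetitions == validation_rep
    if not val_mask.any() or val_mask.all():
        raise ValueError(f"repetition {validation_rep} does not split the training set")
    fit, val = train.select(~val_mask), train.select(val_mask)
    best, best_acc = None, -1.0
    for C in c_grid:
        for gamma in gamma_grid:
            spec = BaselineModelSpec("svm", {"C": C, "gamma": gamma}, seed=seed)
            model = train_baseline(fit, spec)
            pred, _ = predict_baseline(model, val)
            acc = float(np.mean(pred == val.labels))
            if acc > best_acc:
                best, best_acc = {"C": C, "gamma": gamma}, acc
    return best
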