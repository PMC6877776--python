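"""Uniform probabilistic-classifier contract over three model families.

Each family (logistic regression, random forest, multilayer-perceptron
neural network) maps a sparse feature matrix to a per-article probability
of being "considered" for curation.  The evaluation layer is
classifier-blind: it sees only probabilities.

Determinism contract: logistic and forest are fully reproducible given
the seed; the neural net additionally assumes single-threaded execution.
The MLP supports neither class nor sample weights, so class weighting
for that family is realised by seeded weighted oversampling of the
training rows to the same effective class ratio.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .features import FeatureMatrix, FeatureVocabulary

__all__ = [
    "FAMILIES",
    "ClassifierSpec",
    "TrainedModel",
    "make_estimator",
    "train",
    "predict_proba",
    "save_model",
    "load_model",
]

FAMILIES = ("logistic", "random_forest", "neural_net")


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    hyper_parameters: dict[str, Any] = field(default_factory=dict)
    class_weights: dict[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")


def make_estimator(spec: ClassifierSpec):
    """Instantiate the seeded scikit-learn estimator for a spec."""
    hp = dict(spec.hyper_parameters)
    seed = spec.seed % (2**32)
    if spec.family == "logistic":
        return LogisticRegression(class_weight=spec.class_weights, random_state=seed, **hp)
    if spec.family == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(
            class_weight=spec.class_weights, random_state=seed, n_jobs=1, **hp
        )
    hp.setdefault("max_iter", 300)
    if "hidden_layer_sizes" in hp and isinstance(hp["hidden_layer_sizes"], list):
        hp["hidden_layer_sizes"] = tuple(hp["hidden_layer_sizes"])
    return MLPClassifier(random_state=seed, **hp)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    vocabulary: FeatureVocabulary | None
    estimator: Any  # fitted scikit-learn estimator (opaque)


def _weighted_oversample(X, y, weights: dict[int, float], seed: int):
    """Emulate class weights by replicating rows to the weighted ratio."""
    y = np.asarray(y)
    scale = min(weights.values())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls, w in weights.items():
        idx = np.flatnonzero(y == cls)
        target = int(round(len(idx) * w / scale))
        sel = idx
        if target > len(idx):
            extra = rng.choice(idx, size=target - len(idx), replace=True)
            sel = np.concatenate([idx, extra])
        keep.append(sel)
    order = np.sort(np.concatenate(keep))
    Xs = X[order] if sp.issparse(X) else np.asarray(X)[order]
    return Xs, y[order]


def _matrix(X):
    return X.values if isinstance(X, FeatureMatrix) else X


def train(
    spec: ClassifierSpec, X, y, weights: dict[int, float] | None = None
) -> TrainedModel:
    """Fit a model; ``X`` may be a FeatureMatrix (vocabulary remembered)."""
    vocab = X.vocabulary if isinstance(X, FeatureMatrix) else None
    Xv = _matrix(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    weights = weights if weights is not None else spec.class_weights
    if weights is not None and len(set(weights.values())) == 1:
        weights = None  # uniform weights equal the unweighted fit
    eff_spec = ClassifierSpec(
        family=spec.family,
        hyper_parameters=spec.hyper_parameters,
        class_weights=weights,
        seed=spec.seed,
    )
    if spec.family == "neural_net" and weights is not None:
        Xv, y = _weighted_oversample(Xv, y, weights, eff_spec.seed)
    est = make_estimator(eff_spec)
    est.fit(Xv, y)
    return TrainedModel(spec=eff_spec, vocabulary=vocab, estimator=est)


def predict_proba(model: TrainedModel, X) -> np.ndarray:
    """Per-article probability of the 'considered' class, row-aligned."""
    if isinstance(X, FeatureMatrix):
        if model.vocabulary is not None and X.vocabulary.keys != model.vocabulary.keys:
            raise ValueError("feature matrix vocabulary does not match the model's")
    Xv = _matrix(X)
    if Xv.shape[1] != model.estimator.n_features_in_:
        raise ValueError(
            f"matrix has {Xv.shape[1]} features, model expects "
            f"{model.estimator.n_features_in_}"
        )
    classes = list(model.estimator.classes_)
    return model.estimator.predict_proba(Xv)[:, classes.index(1)]


def vocabulary_hash(vocab: FeatureVocabulary | None) -> str:
    if vocab is None:
        return ""
    h = hashlib.sha256("\x1f".join(vocab.keys).encode()).hexdigest()
    return h


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Persist as a versioned binary blob plus a text manifest.

    The manifest (family, hyper-parameters, seed, vocabulary hash and
    size) is the normative description; the blob is an implementation
    detail of this package version.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "family": model.spec.family,
        "hyper_parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.spec.hyper_parameters.items()
        },
        "class_weights": model.spec.class_weights,
        "seed": model.spec.seed,
        "vocabulary_hash": vocabulary_hash(model.vocabulary),
        "n_features": len(model.vocabulary) if model.vocabulary else None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    with open(directory / "model.pkl", "wb") as fh:
        pickle.dump(model, fh)


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format_version") != 1:
        raise ValueError("unsupported model format version")
    with open(directory / "model.pkl", "rb") as fh:
        model = pickle.load(fh)
    if vocabulary_hash(model.vocabulary) != manifest["vocabulary_hash"]:
        raise ValueError("model blob does not match its manifest vocabulary hash")
    return model
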