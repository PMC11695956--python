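"""Training machinery shared by the two screening classifiers.

A fixed 70/15/15 stratified split, SMOTE oversampling of the training
partition only, a trio of tree ensembles (gradient boosting, random
forest, extremely randomised trees), and split-count feature importance
(how often each feature is used in a decision node across all trees).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ALGORITHMS",
    "ModelBundle",
    "stratified_split",
    "smote_oversample",
    "train_classifier",
    "feature_importance",
    "save_bundle",
    "load_bundle",
]

ALGORITHMS = ("gboost", "rf", "et")

DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "gboost": dict(n_estimators=300, learning_rate=0.1, max_depth=3),
    "rf": dict(n_estimators=500, n_jobs=1),
    "et": dict(n_estimators=500, n_jobs=1),
}


@dataclass
class ModelBundle:
    """A fitted classifier with everything needed to apply it safely."""

    task: str  # "questionnaire_binary" | "saturation_3class"
    algorithm: str
    feature_names: list[str]
    model: Any = field(repr=False)
    classes: list = field(default_factory=list)
    split_seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def _check(self, X: np.ndarray, feature_names=None) -> np.ndarray:
        if self.model is None:
            raise ValueError("model not trained")
        if feature_names is not None and list(feature_names) != list(self.feature_names):
            raise ValueError("feature names mismatch with the trained model")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def predict(self, X, feature_names=None) -> np.ndarray:
        return self.model.predict(self._check(X, feature_names))

    def predict_proba(self, X, feature_names=None) -> np.ndarray:
        return self.model.predict_proba(self._check(X, feature_names))


def stratified_split(X, y, seed: int, min_class_size: int = 20):
    """Split into 70% train / 15% validation / 15% test, stratified by label.

    Returns ``(X_tr, y_tr), (X_va, y_va), (X_te, y_te)``; deterministic for
    a fixed seed, with per-class counts within one case of exact
    proportionality.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < min_class_size:
        raise ValueError("insufficient class support")
    idx = np.arange(len(y))
    tr, rest = train_test_split(idx, test_size=0.30, random_state=seed, stratify=y)
    va, te = train_test_split(rest, test_size=0.50, random_state=seed, stratify=y[rest])
    return (X[tr], y[tr]), (X[va], y[va]), (X[te], y[te])


def smote_oversample(X_train, y_train, k: int = 5, seed: int = 0):
    """Balance a training set by synthetic minority oversampling.

    Every class is raised to the majority count; each synthetic row is a
    convex combination ``x + u * (neighbor - x)``, ``u ~ U[0, 1)``, of a
    minority sample and one of its ``k`` nearest same-class neighbours.
    An already-balanced input is returned unchanged.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    if (counts == target).all():
        return X, y
    rng = np.random.default_rng(seed)
    new_X = [X]
    new_y = [y]
    for cls, cnt in zip(classes, counts):
        need = target - cnt
        if need == 0:
            continue
        Xc = X[y == cls]
        if cnt <= k:
            raise ValueError("too few minority samples for k neighbors")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, neigh = nn.kneighbors(Xc)  # column 0 is the sample itself
        base = rng.integers(0, cnt, size=need)
        pick = neigh[base, rng.integers(1, k + 1, size=need)]
        u = rng.random(need)[:, None]
        new_X.append(Xc[base] + u * (Xc[pick] - Xc[base]))
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)


def _build_estimator(algorithm: str, seed: int, hyperparameters: dict | None):
    params = dict(DEFAULT_HYPERPARAMETERS.get(algorithm, {}))
    if hyperparameters:
        params.update(hyperparameters)
    if algorithm == "gboost":
        return GradientBoostingClassifier(random_state=seed, **params)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "et":
        return ExtraTreesClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def train_classifier(
    train,
    valid,
    algorithm: str,
    seed: int,
    task: str = "generic",
    feature_names: list[str] | None = None,
    hyperparameters: dict | None = None,
) -> ModelBundle:
    """Fit one tree ensemble on a (balanced) training set.

    ``train`` and ``valid`` are ``(X, y)`` pairs; the validation set must
    be untouched by oversampling. For gradient boosting it drives early
    stopping (the boosting length minimising validation log-loss); for the
    bagged ensembles it only records a held-out accuracy in the bundle
    metadata. Deterministic for a fixed seed.
    """
    X_tr, y_tr = train
    X_tr = np.asarray(X_tr, dtype=float)
    y_tr = np.asarray(y_tr)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("single-class training set")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X_tr.shape[1])]
    est = _build_estimator(algorithm, seed, hyperparameters)
    est.fit(X_tr, y_tr)
    classes_, class_counts = np.unique(y_tr, return_counts=True)
    meta = {"train_class_counts": dict(zip(map(str, classes_), map(int, class_counts)))}
    if algorithm == "gboost" and valid is not None:
        X_va = np.asarray(valid[0], dtype=float)
        y_va = np.asarray(valid[1])
        losses = [
            log_loss(y_va, proba, labels=est.classes_)
            for proba in est.staged_predict_proba(X_va)
        ]
        best = int(np.argmin(losses)) + 1
        meta["n_estimators_used"] = best
        if best < est.n_estimators:
            est = _build_estimator(algorithm, seed, {**(hyperparameters or {}), "n_estimators": best})
            est.fit(X_tr, y_tr)
    if valid is not None:
        X_va, y_va = valid
        meta["valid_accuracy"] = float(np.mean(est.predict(np.asarray(X_va, float)) == y_va))
    return ModelBundle(
        task=task,
        algorithm=algorithm,
        feature_names=list(feature_names),
        model=est,
        classes=list(est.classes_),
        split_seed=seed,
        metadata=meta,
    )


def _tree_split_counts(tree, n_features: int) -> np.ndarray:
    counts = np.zeros(n_features, dtype=np.int64)
    feat = tree.tree_.feature
    used = feat[feat >= 0]  # leaves are -2
    np.add.at(counts, used, 1)
    return counts


def feature_importance(bundle: ModelBundle) -> list[tuple[str, int]]:
    """Split-count importance: times each feature appears as a decision
    node across every tree of the ensemble, descending, ties alphabetical."""
    if bundle.model is None:
        raise ValueError("model not trained")
    n = len(bundle.feature_names)
    counts = np.zeros(n, dtype=np.int64)
    estimators = np.asarray(bundle.model.estimators_).ravel()
    for tree in estimators:
        counts += _tree_split_counts(tree, n)
    order = sorted(range(n), key=lambda i: (-counts[i], bundle.feature_names[i]))
    return [(bundle.feature_names[i], int(counts[i])) for i in order]


_BUNDLE_FORMAT_VERSION = 1


def save_bundle(bundle: ModelBundle, path) -> None:
    """Persist a bundle as a versioned joblib archive with a config hash."""
    payload = {
        "format_version": _BUNDLE_FORMAT_VERSION,
        "task": bundle.task,
        "algorithm": bundle.algorithm,
        "feature_names": bundle.feature_names,
        "classes": bundle.classes,
        "split_seed": bundle.split_seed,
        "metadata": bundle.metadata,
        "model": bundle.model,
    }
    payload["config_hash"] = hashlib.sha256(
        json.dumps(
            {k: payload[k] for k in ("task", "algorithm", "feature_names", "classes")},
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()
    joblib.dump(payload, path)


def load_bundle(path) -> ModelBundle:
    payload = joblib.load(path)
    if payload.get("format_version") != _BUNDLE_FORMAT_VERSION:
        raise ValueError("unsupported model archive version")
    return ModelBundle(
        task=payload["task"],
        algorithm=payload["algorithm"],
        feature_names=payload["feature_names"],
        model=payload["model"],
        classes=payload["classes"],
        split_seed=payload["split_seed"],
        metadata=payload["metadata"],
    )
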