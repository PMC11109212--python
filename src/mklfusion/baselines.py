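"""Comparison models: unimodal linear SVM, early fusion, and stacking.

Three reference points bracket the kernel-combination model:

* unimodal — a linear SVM per modality, establishing how much signal each
  modality carries on its own;
* early fusion — one linear SVM on the horizontal concatenation of all
  included modalities.  Because widths differ by orders of magnitude (84
  structural features next to thousands of connectivity edges), features are
  z-scored with train statistics before concatenation by default, so the
  narrow modality is not drowned by the wide ones;
* late fusion (stacked generalization) — per-modality SVMs produce
  out-of-fold decision scores on the train set, and a logistic meta-learner
  combines them.  Cross-modality interactions are only visible to the
  meta-learner through one scalar per modality, which is the structural
  reason this family cannot exploit feature-level synergy.

All base learners are hinge-loss linear SVMs at a single fixed C (default 1,
no inner tuning), matching the flat design of the evaluation protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .synthetic import MultimodalDataset

__all__ = [
    "LinearModel",
    "fit_linear_svm",
    "linear_scores",
    "concat_features",
    "zscore_train",
    "stacked_generalization_fit",
    "stacked_scores",
]


@dataclass
class LinearModel:
    """A fitted linear decision function ``x -> w @ x + b``."""

    weights: np.ndarray
    bias: float
    model_family: str  # "svm" | "logistic"
    regularization: float
    train_subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not (np.all(np.isfinite(self.weights)) and np.isfinite(self.bias)):
            raise ValueError("non-finite weights or bias")
        if self.regularization <= 0:
            raise ValueError(f"regularization must be positive, got {self.regularization}")
        if self.model_family not in ("svm", "logistic"):
            raise ValueError(f"unknown model_family {self.model_family!r}")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "model_family": self.model_family,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "regularization": self.regularization,
            "train_subjects": list(self.train_subjects),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LinearModel":
        from .mkl import _read_json_source

        doc = json.loads(_read_json_source(source))
        return cls(
            weights=np.array(doc["weights"]),
            bias=doc["bias"],
            model_family=doc["model_family"],
            regularization=doc["regularization"],
            train_subjects=tuple(doc["train_subjects"]),
        )


def fit_linear_svm(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    train_subjects: tuple[str, ...] = (),
) -> LinearModel:
    """Soft-margin hinge-loss linear SVM exposing primal weights.

    Deterministic given its inputs (libsvm's SMO with a fixed working-set
    rule; no random state enters the linear-kernel path).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(X, y)
    # sklearn orients coef_ toward its classes_[1]; flip if that is -1
    sign = 1.0 if clf.classes_[1] > 0 else -1.0
    return LinearModel(
        weights=sign * clf.coef_.ravel(),
        bias=sign * float(clf.intercept_[0]),
        model_family="svm",
        regularization=float(C),
        train_subjects=tuple(train_subjects),
    )


def linear_scores(model: LinearModel, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} != weight length {model.weights.shape[0]}"
        )
    return X @ model.weights + model.bias


def zscore_train(
    X_train: np.ndarray, X_test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-feature z-scoring by train statistics; constant features map to 0."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z_train = np.where(sd > 0, (X_train - mu) / sd_safe, 0.0)
    Z_test = None
    if X_test is not None:
        Z_test = np.where(sd > 0, (X_test - mu) / sd_safe, 0.0)
    return Z_train, Z_test


def concat_features(
    dataset: MultimodalDataset,
    include_modalities: list[str] | None = None,
    train_idx: np.ndarray | None = None,
    scale: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Early-fusion design matrix: modalities side by side, optionally z-scored.

    Scaling statistics come from ``train_idx`` rows (all rows when omitted)
    and are applied to every row, so test rows see only train information.
    Feature labels are prefixed with their modality name.
    """
    include = include_modalities if include_modalities is not None else dataset.modality_names
    if not include:
        raise ValueError("include_modalities must name at least one modality")
    blocks, labels = [], []
    for name in include:
        mod = dataset.modality(name)  # raises KeyError for unknown names
        X = mod.X
        if scale:
            ref = X if train_idx is None else X[np.asarray(train_idx, dtype=int)]
            mu = ref.mean(axis=0)
            sd = ref.std(axis=0)
            sd_safe = np.where(sd > 0, sd, 1.0)
            X = np.where(sd > 0, (X - mu) / sd_safe, 0.0)
        blocks.append(X)
        labels.extend(f"{name}:{lab}" for lab in mod.feature_labels)
    return np.hstack(blocks), labels


def stacked_generalization_fit(
    dataset: MultimodalDataset,
    train_idx: np.ndarray,
    include_modalities: list[str] | None = None,
    inner_folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> tuple[LinearModel, dict[str, LinearModel]]:
    """Late fusion: per-modality SVMs under a logistic meta-learner.

    Meta-features are out-of-fold SVM decision scores on the train set
    (stratified ``inner_folds``-fold); the meta-learner is an L2 logistic
    regression.  Base models are then refit on the full train set for test
    scoring.  Collinear meta-features (e.g. duplicated modalities) are
    tolerated thanks to the ridge penalty.
    """
    include = include_modalities if include_modalities is not None else dataset.modality_names
    train_idx = np.asarray(train_idx, dtype=int)
    y_train = dataset.labels[train_idx]
    counts = [np.sum(y_train == c) for c in (-1, 1)]
    if min(counts) < inner_folds:
        raise ValueError(
            f"cannot stratify {inner_folds} inner folds with class counts {counts}"
        )
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    scaled = {}
    for name in include:
        X = dataset.modality(name).X[train_idx]
        scaled[name], _ = zscore_train(X)

    meta = np.zeros((len(train_idx), len(include)))
    for tr, va in skf.split(np.zeros(len(train_idx)), y_train):
        for j, name in enumerate(include):
            X = dataset.modality(name).X[train_idx]
            Z_tr, Z_va = zscore_train(X[tr], X[va])
            base = fit_linear_svm(Z_tr, y_train[tr], C=C)
            meta[va, j] = linear_scores(base, Z_va)

    logit = LogisticRegression(C=1.0, max_iter=5000)  # default L2 ridge
    logit.fit(meta, y_train)
    sign = 1.0 if logit.classes_[1] > 0 else -1.0
    ids = np.asarray(dataset.subject_ids)[train_idx]
    meta_model = LinearModel(
        weights=sign * logit.coef_.ravel(),
        bias=sign * float(logit.intercept_[0]),
        model_family="logistic",
        regularization=1.0,
        train_subjects=tuple(ids),
    )
    base_models = {
        name: fit_linear_svm(scaled[name], y_train, C=C, train_subjects=tuple(ids))
        for name in include
    }
    return meta_model, base_models


def stacked_scores(
    meta_model: LinearModel,
    base_models: dict[str, LinearModel],
    dataset: MultimodalDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    include_modalities: list[str] | None = None,
) -> np.ndarray:
    """Test-set decision scores of a fitted stacking ensemble."""
    include = include_modalities if include_modalities is not None else list(base_models)
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    meta = np.zeros((len(test_idx), len(include)))
    for j, name in enumerate(include):
        X = dataset.modality(name).X
        _, Z_te = zscore_train(X[train_idx], X[test_idx])
        meta[:, j] = linear_scores(base_models[name], Z_te)
    return linear_scores(meta_model, meta)
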