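"""Hyperdimensional classifier: encoding, training, retraining, prediction.

A sample with F feature values is encoded by mapping each value to its
level vector, rotating that vector by the feature's position (the first
feature is not rotated, the second is rotated by one position, and so on),
and bundling (element-wise summing) the F rotated vectors.  Each class is
represented by the bundle of the encodings of its training samples; this
set of class vectors is the associative memory.  A sample is predicted as
the class whose vector is closest in cosine similarity.

Bundling many samples introduces crosstalk noise; *retraining* mitigates
it: every misclassified training sample has its encoding subtracted from
the wrongly-predicted class vector and added to its true class vector.
Passes repeat until the training error count stops changing or the pass
budget R is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dataset import ProfileDataset
from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    StratificationError,
    UndefinedSimilarityError,
)
from .vsa import LevelRegistry, generate_levels

__all__ = [
    "HDModel",
    "CVResult",
    "encode_sample",
    "train",
    "retrain",
    "predict",
    "evaluate",
    "cross_validate",
]


@dataclass
class HDModel:
    """Trained associative memory: one accumulated hypervector per class.

    ``class_vectors[i]`` is the (integer) vector for ``classes[i]``;
    classes are kept in sorted label order, which is also the prediction
    tie-break order.  ``adjustments`` logs every retraining update as
    ``(pass_index, sample_position, wrong_class_index, true_class_index)``
    so the final vectors can be reconciled exactly against the initial
    bundles.
    """

    registry: LevelRegistry
    classes: tuple
    class_vectors: np.ndarray
    initial_class_vectors: np.ndarray
    max_retrain: int = 0
    retrain_iterations_used: int = 0
    training_error_trace: list = field(default_factory=list)
    adjustments: list = field(default_factory=list)


@dataclass(frozen=True)
class CVResult:
    """Outcome of stratified k-fold cross-validation."""

    mean_accuracy: float
    fold_accuracies: tuple
    fold_retrain_iterations: tuple

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracies)


# ---------------------------------------------------------------------------
# encoding

def _encode_matrix(registry: LevelRegistry, X: np.ndarray) -> np.ndarray:
    """Encode an (n_samples, F) value matrix into (n_samples, d) hypervectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    idx = registry.value_to_index(X)
    d = registry.dimensionality
    out = np.zeros((X.shape[0], d), dtype=np.int64)
    for n in range(X.shape[1]):
        out += np.roll(registry.levels[idx[:, n]].astype(np.int64), n % d, axis=1)
    return out


def encode_sample(registry: LevelRegistry, values) -> np.ndarray:
    """Encode one sample's F feature values into a single hypervector.

    Feature ``n`` contributes its value's level vector rotated by
    ``n mod d`` positions; feature 0 is unrotated.  The result is the
    bundle (element-wise sum) of the F rotated level vectors.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise InvalidInputError("encode_sample expects a 1-D value sequence")
    if values.size == 0:
        raise InvalidInputError("cannot encode a sample with zero features")
    return _encode_matrix(registry, values[None, :])[0]


# ---------------------------------------------------------------------------
# internal fast paths operating on precomputed encodings

def _scores(class_vectors: np.ndarray, enc: np.ndarray, classes) -> np.ndarray:
    """Cosine similarity of each encoding against each class vector."""
    norms = np.linalg.norm(class_vectors.astype(float), axis=1)
    if np.any(norms == 0.0):
        bad = classes[int(np.flatnonzero(norms == 0.0)[0])]
        raise UndefinedSimilarityError(f"class vector for {bad!r} is all-zero")
    enc = np.atleast_2d(enc).astype(float)
    enc_norms = np.linalg.norm(enc, axis=1)
    if np.any(enc_norms == 0.0):
        raise UndefinedSimilarityError("sample encoding is all-zero")
    return (enc @ class_vectors.T.astype(float)) / np.outer(enc_norms, norms)


def _predict_indices(class_vectors: np.ndarray, enc: np.ndarray, classes) -> np.ndarray:
    # argmax returns the first maximum; classes are sorted, so exact cosine
    # ties resolve to the lexicographically smaller label
    return np.argmax(_scores(class_vectors, enc, classes), axis=1)


def _train_from_encodings(enc: np.ndarray, y_idx: np.ndarray, n_classes: int) -> np.ndarray:
    cv = np.zeros((n_classes, enc.shape[1]), dtype=np.int64)
    for ci in range(n_classes):
        cv[ci] = enc[y_idx == ci].sum(axis=0)
    return cv


def _error_count(class_vectors, enc, y_idx, classes) -> int:
    return int(np.sum(_predict_indices(class_vectors, enc, classes) != y_idx))


def _retrain_from_encodings(class_vectors, enc, y_idx, R, classes):
    """Online retraining passes; returns (vectors, passes_used, trace, adjustments)."""
    cv = class_vectors.copy()
    prev = 0
    curr = _error_count(cv, enc, y_idx, classes)
    trace = [curr]
    adjustments: list = []
    passes = 0
    while curr != prev and passes < R:
        for i in range(enc.shape[0]):
            ci = int(_predict_indices(cv, enc[i : i + 1], classes)[0])
            ti = int(y_idx[i])
            if ci != ti:
                cv[ci] -= enc[i]
                cv[ti] += enc[i]
                adjustments.append((passes, i, ci, ti))
        prev = curr
        curr = _error_count(cv, enc, y_idx, classes)
        trace.append(curr)
        passes += 1
    return cv, passes, trace, adjustments


# ---------------------------------------------------------------------------
# public operations on ProfileDataset

def _check_trainable(dataset: ProfileDataset) -> None:
    if dataset.n_samples == 0:
        raise InvalidInputError("training dataset is empty")
    if dataset.labels is None:
        raise InvalidInputError("training dataset has no class labels")
    counts = dataset.labels.value_counts()
    if (counts < 1).any():
        raise InvalidInputError("every class needs at least one training sample")
    if len(counts) < 2:
        raise InvalidInputError("training requires at least 2 distinct class labels")


def _label_indices(dataset: ProfileDataset, classes) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[c] for c in dataset.labels], dtype=np.int64)


def train(training: ProfileDataset, registry: LevelRegistry) -> HDModel:
    """Build class vectors by bundling the encodings of each class's samples.

    No retraining is applied; call :func:`retrain` afterwards to mitigate
    bundling noise.
    """
    _check_trainable(training)
    classes = tuple(training.classes)
    enc = _encode_matrix(registry, training.values)
    y_idx = _label_indices(training, classes)
    cv = _train_from_encodings(enc, y_idx, len(classes))
    return HDModel(
        registry=registry,
        classes=classes,
        class_vectors=cv,
        initial_class_vectors=cv.copy(),
    )


def retrain(model: HDModel, training: ProfileDataset, R: int = 10) -> HDModel:
    """Run up to ``R`` error-mitigation passes over the training set.

    Samples are visited in dataset order; each misclassification
    immediately subtracts the sample's encoding from the wrongly-predicted
    class vector and adds it to the true class vector.  The loop stops when
    the full-training-set error count equals the previous pass's count, or
    after ``R`` passes.  The error trace (initial count plus one entry per
    pass) and the adjustment log are recorded on the returned model.
    """
    if R < 0:
        raise InvalidParameterError(f"retraining budget R must be >= 0, got {R}")
    _check_trainable(training)
    enc = _encode_matrix(model.registry, training.values)
    y_idx = _label_indices(training, model.classes)
    cv, passes, trace, adjustments = _retrain_from_encodings(
        model.class_vectors, enc, y_idx, R, model.classes
    )
    return HDModel(
        registry=model.registry,
        classes=model.classes,
        class_vectors=cv,
        initial_class_vectors=model.initial_class_vectors.copy(),
        max_retrain=R,
        retrain_iterations_used=passes,
        training_error_trace=trace,
        adjustments=adjustments,
    )


def predict(model: HDModel, values) -> object:
    """Class label of the class vector closest (by cosine) to the encoding.

    Exact ties resolve to the lexicographically smaller label.
    """
    enc = encode_sample(model.registry, np.asarray(values, dtype=float))
    ci = int(_predict_indices(model.class_vectors, enc[None, :], model.classes)[0])
    return model.classes[ci]


def evaluate(model: HDModel, dataset: ProfileDataset) -> tuple[float, int]:
    """Accuracy fraction and error count of ``model`` on ``dataset``."""
    if dataset.n_samples == 0:
        raise InvalidInputError("cannot evaluate on an empty dataset")
    if dataset.labels is None:
        raise InvalidInputError("evaluation dataset has no class labels")
    enc = _encode_matrix(model.registry, dataset.values)
    y_idx = _label_indices(dataset, model.classes)
    errors = _error_count(model.class_vectors, enc, y_idx, model.classes)
    return (dataset.n_samples - errors) / dataset.n_samples, errors


def cross_validate(
    dataset: ProfileDataset,
    k: int = 5,
    d: int = 10_000,
    L: int = 1_000,
    R: int = 10,
    seed: int | None = None,
    registry: LevelRegistry | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the HD classifier.

    The level registry is built once from the dataset's observed value
    range and shared across folds (levels encode values, not samples), so
    fold accuracies are comparable.  The fold partition is stratified by
    class label and deterministic for a fixed ``seed``.
    """
    if k < 2:
        raise InvalidParameterError(f"need at least 2 folds, got k={k}")
    _check_trainable(dataset)
    counts = dataset.labels.value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise StratificationError(
            f"classes smaller than k={k} folds: {dict(small)}"
        )
    if registry is None:
        vmin, vmax = dataset.value_range()
        registry = generate_levels(d, L, v_min=min(vmin, 0.0), v_max=vmax, seed=seed)

    enc = _encode_matrix(registry, dataset.values)
    classes = tuple(dataset.classes)
    y_idx = _label_indices(dataset, classes)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=None if seed is None else seed % (2**32))
    accs: list[float] = []
    iters: list[int] = []
    for train_pos, test_pos in skf.split(np.zeros(len(y_idx)), y_idx):
        cv0 = _train_from_encodings(enc[train_pos], y_idx[train_pos], len(classes))
        cvr, passes, _, _ = _retrain_from_encodings(
            cv0, enc[train_pos], y_idx[train_pos], R, classes
        )
        errors = _error_count(cvr, enc[test_pos], y_idx[test_pos], classes)
        accs.append((len(test_pos) - errors) / len(test_pos))
        iters.append(passes)
    return CVResult(
        mean_accuracy=float(np.mean(accs)),
        fold_accuracies=tuple(accs),
        fold_retrain_iterations=tuple(iters),
    )
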