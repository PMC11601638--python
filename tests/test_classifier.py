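"""Tests for encoding, training, retraining, prediction and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from hdselect import (
    InvalidInputError,
    InvalidParameterError,
    ProfileDataset,
    StratificationError,
    bundle,
    cross_validate,
    encode_sample,
    evaluate,
    generate_levels,
    predict,
    retrain,
    rotate,
    train,
)
from hdselect.classifier import _encode_matrix


def _dataset(matrix, labels, columns=None):
    matrix = np.asarray(matrix, dtype=float)
    columns = columns or [f"f{i}" for i in range(matrix.shape[1])]
    idx = [f"s{i}" for i in range(matrix.shape[0])]
    return ProfileDataset(
        abundance=pd.DataFrame(matrix, index=idx, columns=columns),
        labels=pd.Series(labels, index=idx),
    )


class TestEncoding:
    def test_single_feature_is_unrotated_level_vector(self, small_registry):
        enc = encode_sample(small_registry, [37.0])
        idx = small_registry.value_to_index(37.0)
        assert np.array_equal(enc, small_registry.level(idx))

    def test_two_features_same_level_compose_by_rotation(self, small_registry):
        lvl = small_registry.level(small_registry.value_to_index(50.0))
        enc = encode_sample(small_registry, [50.0, 50.0])
        assert np.array_equal(enc, bundle([lvl, rotate(lvl, 1)]))

    def test_binary_sample_encoding(self):
        reg = generate_levels(64, 2, v_min=0.0, v_max=1.0, seed=8)
        enc = encode_sample(reg, [0, 1])
        expected = bundle([reg.level(0), rotate(reg.level(1), 1)])
        assert np.array_equal(enc, expected)

    def test_matrix_encoding_matches_per_sample(self, small_registry):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 100, size=(5, 7))
        mat = _encode_matrix(small_registry, X)
        for i in range(5):
            assert np.array_equal(mat[i], encode_sample(small_registry, X[i]))


class TestTrain:
    def test_class_vectors_are_per_class_encoding_sums(self, small_registry):
        ds = _dataset([[10, 20], [30, 40], [50, 60]], ["a", "a", "b"])
        model = train(ds, small_registry)
        enc = _encode_matrix(small_registry, ds.values)
        assert model.classes == ("a", "b")
        assert np.array_equal(model.class_vectors[0], enc[0] + enc[1])
        assert np.array_equal(model.class_vectors[1], enc[2])

    def test_training_requires_two_classes(self, small_registry):
        ds = _dataset([[1, 2], [3, 4]], ["a", "a"])
        with pytest.raises(InvalidInputError):
            train(ds, small_registry)


class TestPredict:
    def test_matches_bruteforce_cosine_argmax(self, small_registry):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 100, size=(12, 5))
        ds = _dataset(X, ["a", "b", "c"] * 4)
        model = train(ds, small_registry)
        for _ in range(20):
            sample = rng.uniform(0, 100, size=5)
            enc = encode_sample(small_registry, sample).astype(float)
            cos = [
                float(enc @ cv) / (np.linalg.norm(enc) * np.linalg.norm(cv.astype(float)))
                for cv in model.class_vectors
            ]
            assert predict(model, sample) == model.classes[int(np.argmax(cos))]

    def test_exact_tie_breaks_to_smaller_label(self, small_registry):
        ds = _dataset([[10, 20], [10, 20]], ["b", "a"])
        model = train(ds, small_registry)  # both class vectors identical
        assert predict(model, [10, 20]) == "a"


class TestRetrain:
    def test_zero_initial_errors_returns_unchanged(self, small_registry):
        ds = _dataset([[0, 0], [100, 100]], ["a", "b"])
        model = train(ds, small_registry)
        out = retrain(model, ds, R=10)
        assert out.retrain_iterations_used == 0
        assert np.array_equal(out.class_vectors, model.class_vectors)
        assert out.training_error_trace == [0]

    def test_zero_budget_runs_no_passes(self, small_registry):
        rng = np.random.default_rng(3)
        ds = _dataset(rng.uniform(0, 100, (10, 4)), ["a", "b"] * 5)
        model = train(ds, small_registry)
        out = retrain(model, ds, R=0)
        assert out.retrain_iterations_used == 0
        assert np.array_equal(out.class_vectors, model.class_vectors)

    def test_negative_budget_rejected(self, small_registry):
        ds = _dataset([[1, 2], [3, 4]], ["a", "b"])
        with pytest.raises(InvalidParameterError):
            retrain(train(ds, small_registry), ds, R=-1)

    def test_adjustment_log_reconciles_class_vectors(self, small_registry):
        rng = np.random.default_rng(4)
        ds = _dataset(rng.uniform(0, 100, (20, 6)), ["a", "b", "c", "d"] * 5)
        model = retrain(train(ds, small_registry), ds, R=10)
        enc = _encode_matrix(small_registry, ds.values)
        replay = model.initial_class_vectors.astype(np.int64).copy()
        for _, i, wrong, true in model.adjustments:
            replay[wrong] -= enc[i]
            replay[true] += enc[i]
        assert np.array_equal(replay, model.class_vectors)


class TestEvaluate:
    def test_accuracy_fractions(self, small_registry):
        ds = _dataset([[0, 0], [100, 100], [0, 0], [100, 100]], ["a", "b", "a", "b"])
        model = train(ds, small_registry)
        acc, errors = evaluate(model, ds)
        assert acc == 1.0 and errors == 0
        flipped = _dataset([[0, 0], [100, 100], [0, 0], [100, 100]], ["b", "a", "b", "a"])
        acc, errors = evaluate(model, flipped)
        assert acc == 0.0 and errors == 4

    def test_empty_dataset_rejected(self, small_registry):
        ds = _dataset([[1, 2], [3, 4]], ["a", "b"])
        model = train(ds, small_registry)
        with pytest.raises(InvalidInputError):
            evaluate(model, ds.select_samples([]))


class TestCrossValidate:
    def test_partition_is_disjoint_stratified_and_deterministic(self, planted_binary):
        ds, _ = planted_binary(seed=5, n_case=10, n_control=10, n_species=12)
        a = cross_validate(ds, k=5, d=256, L=2, R=3, seed=9)
        b = cross_validate(ds, k=5, d=256, L=2, R=3, seed=9)
        assert a == b
        assert a.n_folds == 5
        assert a.mean_accuracy == pytest.approx(np.mean(a.fold_accuracies))

    def test_small_class_raises_stratification_error(self, small_registry):
        ds = _dataset(np.random.default_rng(0).uniform(0, 100, (6, 3)), ["a"] * 4 + ["b"] * 2)
        with pytest.raises(StratificationError):
            cross_validate(ds, k=5, d=64, L=4)

    def test_disjoint_planted_patterns_classify_above_09(self):
        # two classes whose planted feature blocks never overlap: trivially separable
        rng = np.random.default_rng(0)
        accs = []
        for seed in range(5):
            n, F = 40, 12
            X = np.zeros((n, F))
            X[: n // 2, :4] = (rng.random((n // 2, 4)) < 0.9).astype(float)
            X[n // 2 :, 4:8] = (rng.random((n // 2, 4)) < 0.9).astype(float)
            ds = _dataset(X, ["case"] * (n // 2) + ["control"] * (n // 2))
            accs.append(cross_validate(ds, k=5, d=1024, L=2, R=10, seed=seed).mean_accuracy)
        assert np.mean(accs) >= 0.9
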