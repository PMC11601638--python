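"""Tests for backward variable elimination and sub-optimal model tracking."""

import numpy as np
import pandas as pd
import pytest

from hdselect import (
    CandidateRecord,
    InvalidParameterError,
    OracleDomainError,
    ProfileDataset,
    SelectionConfig,
    backward_eliminate,
    suboptimal_best,
    subset_seed,
)


def _oracle_dataset(features):
    """Unlabeled placeholder dataset: oracle-driven runs never train on it."""
    ab = pd.DataFrame(np.zeros((2, len(features))), columns=features, index=["s0", "s1"])
    return ProfileDataset(abundance=ab)


FIGURE_TRACE = {
    frozenset(["F1", "F2", "F3", "F4", "F5"]): 0.72,
    # iteration 1: best 93% (missing F2); 91% (missing F3) inside the 5% band;
    # 68% (missing F1) below the 70% threshold
    frozenset(["F2", "F3", "F4", "F5"]): 0.68,
    frozenset(["F1", "F3", "F4", "F5"]): 0.93,
    frozenset(["F1", "F2", "F4", "F5"]): 0.91,
    frozenset(["F1", "F2", "F3", "F5"]): 0.80,
    frozenset(["F1", "F2", "F3", "F4"]): 0.75,
    # iteration 2: best 90% (missing F5); the others fail the threshold
    frozenset(["F4", "F5"]): 0.60,
    frozenset(["F1", "F5"]): 0.65,
    frozenset(["F1", "F4"]): 0.90,
    # iteration 3 (never needed to change the outcome): single-feature models
    frozenset(["F1"]): 0.75,
    frozenset(["F4"]): 0.72,
}


class TestWorkedTrace:
    def test_band_multi_removal_recovers_two_features(self):
        ds = _oracle_dataset(["F1", "F2", "F3", "F4", "F5"])
        cfg = SelectionConfig(accuracy_threshold=0.70, uncertainty_pct=5.0)
        res = backward_eliminate(ds, cfg, model_oracle=FIGURE_TRACE)
        assert set(res.selected_features) == {"F1", "F4"}
        assert res.bucket == ("F2", "F3", "F5")
        assert res.best_accuracy == pytest.approx(0.93)
        assert set(res.best_feature_set) == {"F1", "F3", "F4", "F5"}

    def test_full_model_below_threshold_stops_immediately(self):
        ds = _oracle_dataset(["F1", "F2"])
        oracle = {frozenset(["F1", "F2"]): 0.55}
        res = backward_eliminate(ds, SelectionConfig(accuracy_threshold=0.70), oracle)
        assert res.selected_features == ("F1", "F2")
        assert res.bucket == ()
        assert len(res.history) == 1 and res.history[0].below_threshold

    def test_oracle_domain_error_when_subset_missing(self):
        ds = _oracle_dataset(["F1", "F2"])
        oracle = {frozenset(["F1", "F2"]): 0.9}
        with pytest.raises(OracleDomainError):
            backward_eliminate(ds, SelectionConfig(), oracle)

    def test_single_removal_mode_removes_one_per_iteration(self):
        ds = _oracle_dataset(["F1", "F2", "F3"])
        oracle = {
            frozenset(["F1", "F2", "F3"]): 0.80,
            frozenset(["F2", "F3"]): 0.85,  # missing F1: iteration best
            frozenset(["F1", "F3"]): 0.84,  # inside any wide band, but not removed
            frozenset(["F1", "F2"]): 0.50,
            frozenset(["F3"]): 0.70,  # missing F2: next best, below previous best
            frozenset(["F2"]): 0.62,
        }
        cfg = SelectionConfig(
            accuracy_threshold=0.60, uncertainty_pct=5.0, multi_removal=False
        )
        res = backward_eliminate(ds, cfg, model_oracle=oracle)
        assert res.bucket == ("F1", "F2")
        assert res.selected_features == ("F3",)


class TestSuboptimal:
    def test_exhaustive_scan_of_records(self):
        recs = [
            CandidateRecord(1, None, ("a", "b", "c", "d", "e"), 0.72, (0.72,)),
            CandidateRecord(2, None, ("a", "b", "c"), 0.71, (0.71,)),
            CandidateRecord(2, None, ("a", "b", "d"), 0.69, (0.69,)),
        ]
        best = suboptimal_best(recs, floor=0.70)
        assert best.features == ("a", "b", "c") and best.accuracy == pytest.approx(0.71)

    def test_absent_when_nothing_clears_floor(self):
        recs = [CandidateRecord(1, None, ("a",), 0.65, (0.65,))]
        assert suboptimal_best(recs, floor=0.70) is None

    def test_single_qualifying_record_wins(self):
        recs = [CandidateRecord(1, None, ("a", "b"), 0.91, (0.91,))]
        assert suboptimal_best(recs, floor=0.70).features == ("a", "b")

    def test_tie_on_size_prefers_higher_accuracy(self):
        recs = [
            CandidateRecord(1, None, ("a", "b"), 0.75, (0.75,)),
            CandidateRecord(1, None, ("c", "d"), 0.80, (0.80,)),
        ]
        assert suboptimal_best(recs, floor=0.70).features == ("c", "d")


class TestRealSelection:
    CFG = dict(dimensionality=256, levels=2, retrain_iterations=3)

    def test_bookkeeping_and_monotone_shrinkage(self, planted_binary):
        ds, _ = planted_binary(seed=1, n_case=15, n_control=15, n_species=8)
        cfg = SelectionConfig(seed=1, **self.CFG)
        res = backward_eliminate(ds, cfg)
        # fold-model count is folds x distinct subsets evaluated
        assert res.models_evaluated == len(res.history) * cfg.folds
        # survivors and bucket partition the initial feature set
        assert set(res.selected_features) | set(res.bucket) == set(ds.feature_names)
        assert set(res.selected_features) & set(res.bucket) == set()
        # per-iteration candidate sets strictly shrink
        sizes = [len(r.features) for r in res.history if r.missing_feature is not None]
        by_iter = {}
        for r in res.history[1:]:
            by_iter.setdefault(r.iteration, set()).add(len(r.features))
        it_sizes = [max(v) for _, v in sorted(by_iter.items())]
        assert it_sizes == sorted(it_sizes, reverse=True)
        assert len(set(it_sizes)) == len(it_sizes)
        if res.history[0].mean_accuracy >= cfg.accuracy_threshold:
            assert res.best_accuracy >= cfg.accuracy_threshold

    def test_column_order_does_not_change_outcome(self, planted_binary):
        ds, _ = planted_binary(seed=2, n_case=12, n_control=12, n_species=6)
        cfg = SelectionConfig(seed=2, **self.CFG)
        res_a = backward_eliminate(ds, cfg)
        shuffled = ds.select_features(list(reversed(ds.feature_names)))
        res_b = backward_eliminate(shuffled, cfg)
        assert set(res_a.selected_features) == set(res_b.selected_features)
        assert set(res_a.bucket) == set(res_b.bucket)
        assert res_a.best_accuracy == pytest.approx(res_b.best_accuracy)

    def test_parallel_equals_serial(self, planted_binary):
        ds, _ = planted_binary(seed=3, n_case=12, n_control=12, n_species=6)
        serial = backward_eliminate(ds, SelectionConfig(seed=3, **self.CFG))
        parallel = backward_eliminate(ds, SelectionConfig(seed=3, max_workers=2, **self.CFG))
        assert serial.selected_features == parallel.selected_features
        assert serial.best_accuracy == pytest.approx(parallel.best_accuracy)


class TestSeeds:
    def test_subset_seed_is_order_independent_and_31_bit(self):
        s1 = subset_seed(7, ["b", "a", "c"])
        s2 = subset_seed(7, ["c", "b", "a"])
        assert s1 == s2
        assert 0 <= s1 < 2**31
        assert subset_seed(8, ["a", "b", "c"]) != s1

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            SelectionConfig(accuracy_threshold=1.5)
        with pytest.raises(InvalidParameterError):
            SelectionConfig(uncertainty_pct=100.0)
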