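"""Stepwise backward variable elimination over HD classification models.

Starting from the full feature set S, each iteration evaluates, by k-fold
cross-validated accuracy, every candidate subset obtained by removing a
single feature.  Candidates below the accuracy threshold T are discarded.
All features whose candidate accuracy reaches the *uncertainty band* —
within u percent of the iteration-best accuracy ACC* — are removed
together (multi-removal; a strict single-removal mode is available).  The
loop stops when no candidate reaches T, when the iteration best falls
below the previous iteration's best (checked after the removal), or when S
is exhausted; the surviving set is reported together with the globally
best-accuracy subset and a *sub-optimal* record: the evaluated subset with
the fewest features whose accuracy still exceeds a floor (70% by default).

Candidate subsets are evaluated with features in canonical sorted order
and with RNG seeds derived from a hash of the subset, so results are
independent of input column order, evaluation order, and parallelism.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed

from .classifier import cross_validate
from .dataset import ProfileDataset
from .exceptions import InvalidInputError, InvalidParameterError, OracleDomainError
from .vsa import generate_levels

__all__ = [
    "SelectionConfig",
    "CandidateRecord",
    "SuboptimalRecord",
    "SelectionResult",
    "backward_eliminate",
    "suboptimal_best",
    "subset_seed",
    "write_ledger",
    "write_summary",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the backward elimination run.

    Parameters
    ----------
    accuracy_threshold
        T, the minimum cross-validated accuracy (fraction) a model must
        reach to stay in play; default 0.60.
    uncertainty_pct
        u, the accuracy uncertainty percentage: every candidate whose
        accuracy is at least ``ACC* * (1 - u/100)`` (and at least T) is
        removed together with the iteration best; default 1.0.
    suboptimal_floor
        Accuracy fraction a subset must strictly exceed to qualify as the
        sub-optimal (fewest-features) model; default 0.70.
    folds
        k for the stratified cross-validation of every candidate model.
    retrain_iterations
        R, the per-model retraining pass budget.
    dimensionality, levels
        d and L of the level registry (use ``levels=2`` for binary data).
    seed
        Global seed; per-subset seeds are derived from it by hashing the
        sorted feature subset.
    max_workers
        Parallel evaluation slots for candidate subsets (results are
        merged deterministically regardless of worker count).
    multi_removal
        If False, remove only the single best candidate per iteration
        (ties broken by feature order) instead of the whole band.
    """

    accuracy_threshold: float = 0.60
    uncertainty_pct: float = 1.0
    suboptimal_floor: float = 0.70
    folds: int = 5
    retrain_iterations: int = 10
    dimensionality: int = 10_000
    levels: int = 1_000
    seed: int = 0
    max_workers: int = 1
    multi_removal: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.accuracy_threshold < 1.0:
            raise InvalidParameterError("accuracy_threshold must be in (0, 1)")
        if not 0.0 <= self.uncertainty_pct < 100.0:
            raise InvalidParameterError("uncertainty_pct must be in [0, 100)")
        if not 0.0 < self.suboptimal_floor < 1.0:
            raise InvalidParameterError("suboptimal_floor must be in (0, 1)")


@dataclass
class CandidateRecord:
    """One evaluated feature subset (the iteration's 'missing feature' view)."""

    iteration: int
    missing_feature: str | None
    features: tuple
    mean_accuracy: float
    fold_accuracies: tuple
    removed: bool = False
    below_threshold: bool = False


@dataclass(frozen=True)
class SuboptimalRecord:
    """Fewest-feature subset whose accuracy strictly exceeds the floor."""

    features: tuple
    accuracy: float


@dataclass
class SelectionResult:
    """Everything the elimination run produced.

    ``selected_features`` is the surviving set; ``bucket`` the removed
    features in removal order; ``history`` one record per evaluated
    subset; ``best_feature_set``/``best_accuracy`` the globally best model
    (ties: fewest features, then lexicographic); ``suboptimal`` the
    fewest-feature model above the floor, if any.
    """

    selected_features: tuple
    bucket: tuple
    history: list
    best_accuracy: float
    best_feature_set: tuple
    models_evaluated: int
    suboptimal: SuboptimalRecord | None
    config: SelectionConfig


def subset_seed(global_seed: int, features: Iterable[str]) -> int:
    """Deterministic 31-bit seed for a feature subset, independent of order."""
    key = f"{global_seed}|" + "|".join(sorted(features))
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _make_evaluator(
    dataset: ProfileDataset,
    config: SelectionConfig,
    model_oracle,
) -> Callable[[tuple], tuple[float, tuple]]:
    """Return fn(features) -> (mean_accuracy, fold_accuracies)."""
    if model_oracle is not None:
        def lookup(features: tuple) -> tuple[float, tuple]:
            key = frozenset(features)
            try:
                if isinstance(model_oracle, Mapping):
                    acc = model_oracle[key]
                else:
                    acc = model_oracle(key)
            except KeyError as exc:
                raise OracleDomainError(
                    f"oracle does not cover subset {sorted(features)}"
                ) from exc
            if acc is None:
                raise OracleDomainError(f"oracle does not cover subset {sorted(features)}")
            return float(acc), (float(acc),)

        return lookup

    vmin, vmax = dataset.value_range()
    registry = generate_levels(
        config.dimensionality,
        config.levels,
        v_min=min(vmin, 0.0),
        v_max=vmax,
        seed=config.seed,
    )

    def evaluate_subset(features: tuple) -> tuple[float, tuple]:
        # canonical sorted order keeps results independent of column order
        sub = dataset.select_features(sorted(features))
        cv = cross_validate(
            sub,
            k=config.folds,
            R=config.retrain_iterations,
            seed=subset_seed(config.seed, features),
            registry=registry,
        )
        return cv.mean_accuracy, cv.fold_accuracies

    return evaluate_subset


def backward_eliminate(
    dataset: ProfileDataset,
    config: SelectionConfig | None = None,
    model_oracle: Mapping | Callable | None = None,
) -> SelectionResult:
    """Run backward variable elimination on ``dataset``.

    ``model_oracle``, when given, replaces HD model training entirely: it
    is a mapping (or callable) from a frozenset of feature names to the
    mean accuracy of the model trained without them, and exists so the
    algorithm's control flow can be exercised against a known trace.
    Querying a subset the oracle does not cover raises
    :class:`OracleDomainError`.
    """
    config = config or SelectionConfig()
    if dataset.n_features < 1:
        raise InvalidInputError("dataset has no features to select from")
    if model_oracle is None and dataset.n_samples == 0:
        raise InvalidInputError("dataset has no samples")

    evaluator = _make_evaluator(dataset, config, model_oracle)
    T = config.accuracy_threshold
    history: list[CandidateRecord] = []

    def run_batch(subsets: Sequence[tuple]) -> list[tuple[float, tuple]]:
        if config.max_workers > 1 and model_oracle is None:
            return Parallel(n_jobs=config.max_workers)(
                delayed(evaluator)(s) for s in subsets
            )
        return [evaluator(s) for s in subsets]

    all_features = tuple(dataset.feature_names)
    full_acc, full_folds = evaluator(all_features)
    history.append(
        CandidateRecord(
            iteration=0,
            missing_feature=None,
            features=all_features,
            mean_accuracy=full_acc,
            fold_accuracies=tuple(full_folds),
            below_threshold=full_acc < T,
        )
    )

    current = list(all_features)
    bucket: list[str] = []
    prev_best = full_acc
    iteration = 0

    if full_acc >= T:
        while current:
            iteration += 1
            subsets = [tuple(f for f in current if f != miss) for miss in current]
            nonempty = [s for s in subsets if s]
            if not nonempty:
                break
            results = run_batch(nonempty)
            records = []
            for miss, feats, (acc, folds) in zip(
                [m for m, s in zip(current, subsets) if s], nonempty, results
            ):
                rec = CandidateRecord(
                    iteration=iteration,
                    missing_feature=miss,
                    features=feats,
                    mean_accuracy=acc,
                    fold_accuracies=tuple(folds),
                    below_threshold=acc < T,
                )
                records.append(rec)
                history.append(rec)
            acc_star = max(r.mean_accuracy for r in records)
            if acc_star < T:
                break
            band = acc_star * (1.0 - config.uncertainty_pct / 100.0)
            if config.multi_removal:
                to_remove = [
                    r.missing_feature
                    for r in records
                    if r.mean_accuracy >= band and r.mean_accuracy >= T
                ]
            else:
                best = min(
                    (r for r in records if r.mean_accuracy == acc_star),
                    key=lambda r: current.index(r.missing_feature),
                )
                to_remove = [best.missing_feature]
            removal_set = set(to_remove)
            for r in records:
                if r.missing_feature in removal_set:
                    r.removed = True
            bucket.extend(f for f in current if f in removal_set)
            current = [f for f in current if f not in removal_set]
            if acc_star < prev_best:
                break
            prev_best = acc_star

    # globally best subset: max accuracy, then fewest features, then lexicographic
    best = min(
        history,
        key=lambda r: (-r.mean_accuracy, len(r.features), tuple(sorted(r.features))),
    )
    n_subsets = len(history)
    models_evaluated = n_subsets if model_oracle is not None else n_subsets * config.folds
    return SelectionResult(
        selected_features=tuple(current),
        bucket=tuple(bucket),
        history=history,
        best_accuracy=best.mean_accuracy,
        best_feature_set=tuple(best.features),
        models_evaluated=models_evaluated,
        suboptimal=suboptimal_best(history, config.suboptimal_floor),
        config=config,
    )


def suboptimal_best(history: Iterable[CandidateRecord], floor: float) -> SuboptimalRecord | None:
    """Fewest-feature evaluated subset with accuracy strictly above ``floor``.

    Ties are broken by higher accuracy, then by lexicographic feature
    list.  Returns ``None`` when no evaluated subset qualifies.
    """
    qualifying = [r for r in history if r.mean_accuracy > floor]
    if not qualifying:
        return None
    best = min(
        qualifying,
        key=lambda r: (len(r.features), -r.mean_accuracy, tuple(sorted(r.features))),
    )
    return SuboptimalRecord(features=tuple(best.features), accuracy=best.mean_accuracy)


# ---------------------------------------------------------------------------
# artefact writers

def write_ledger(result: SelectionResult, path) -> None:
    """Write the per-candidate evaluation ledger as TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "iteration\tmissing_feature\tn_features\tmean_accuracy\t"
            "fold_accuracies\tremoved\tbelow_threshold\n"
        )
        for r in result.history:
            folds = ",".join(f"{a:.6f}" for a in r.fold_accuracies)
            fh.write(
                f"{r.iteration}\t{r.missing_feature or '-'}\t{len(r.features)}\t"
                f"{r.mean_accuracy:.6f}\t{folds}\t{int(r.removed)}\t{int(r.below_threshold)}\n"
            )


def write_summary(result: SelectionResult, path) -> None:
    """Write the selection summary as deterministic JSON."""
    payload = {
        "selected_features": sorted(result.selected_features),
        "bucket": list(result.bucket),
        "best_accuracy": round(result.best_accuracy, 6),
        "best_feature_set": sorted(result.best_feature_set),
        "models_evaluated": result.models_evaluated,
        "suboptimal": None
        if result.suboptimal is None
        else {
            "features": sorted(result.suboptimal.features),
            "accuracy": round(result.suboptimal.accuracy, 6),
        },
        "config": {
            "accuracy_threshold": result.config.accuracy_threshold,
            "uncertainty_pct": result.config.uncertainty_pct,
            "suboptimal_floor": result.config.suboptimal_floor,
            "folds": result.config.folds,
            "retrain_iterations": result.config.retrain_iterations,
            "dimensionality": result.config.dimensionality,
            "levels": result.config.levels,
            "seed": result.config.seed,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
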