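"""Harmonisation, filtering, binarisation and stratification of profiles.

Multi-study relative-abundance tables are merged by keeping only species
detected (abundance > 0 in at least one sample) in *every* study; the
abundance of any excluded species is folded, per sample, into that
sample's ``unclassified`` remainder, so per-sample totals are conserved.
The same conservation rule applies to the low-abundance and low-prevalence
filters.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import ProfileDataset
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "harmonize_studies",
    "filter_low_abundance",
    "filter_low_prevalence",
    "binarize",
    "stratify",
]

_UNCLASSIFIED_NAMES = {"unclassified", "unknown"}


def _split_unclassified(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Separate the unclassified row from a taxa x samples table."""
    mask = table.index.str.lower().isin(_UNCLASSIFIED_NAMES)
    if mask.sum() > 1:
        raise InvalidInputError("multiple unclassified rows in one table")
    if mask.any():
        uncl = table.loc[mask].iloc[0].astype(float)
        species = table.loc[~mask]
    else:
        uncl = pd.Series(0.0, index=table.columns)
        species = table
    return species.astype(float), uncl


def harmonize_studies(
    tables: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame | None = None,
) -> ProfileDataset:
    """Merge per-study taxa x samples tables into one dataset.

    Only species detected (value > 0 in >= 1 sample) in every study are
    kept as features; each excluded species' abundance is added, per
    sample, to that sample's unclassified value.  Sample columns are
    concatenated; a ``study`` column is recorded in the metadata.

    Parameters
    ----------
    tables
        Mapping of study id to MetaPhlAn-style table (rows = species plus
        one ``unclassified`` row, columns = samples, values 0-100).
    metadata
        Optional per-sample table indexed by sample id; a ``class`` column,
        if present, becomes the dataset labels.
    """
    if not tables:
        raise InvalidInputError("no study tables given")
    parts: list[tuple[str, pd.DataFrame, pd.Series]] = []
    detected_sets: list[set] = []
    seen: set = set()
    for study, table in tables.items():
        species, uncl = _split_unclassified(table)
        dup = seen & set(species.columns)
        if dup:
            raise InvalidInputError(f"duplicate sample ids across studies: {sorted(dup)[:5]}")
        seen |= set(species.columns)
        parts.append((study, species, uncl))
        detected_sets.append(set(species.index[(species > 0).any(axis=1)]))

    shared = set.intersection(*detected_sets)
    blocks: list[pd.DataFrame] = []
    uncl_blocks: list[pd.Series] = []
    study_of: dict = {}
    # keep species in first-appearance order for a stable column layout
    ordered = [s for s in parts[0][1].index if s in shared]
    ordered += sorted(shared - set(ordered))
    for study, species, uncl in parts:
        keep = species.reindex(ordered).fillna(0.0)
        dropped = species.loc[~species.index.isin(shared)]
        uncl = uncl.add(dropped.sum(axis=0), fill_value=0.0)
        blocks.append(keep.T)
        uncl_blocks.append(uncl)
        for sid in species.columns:
            study_of[sid] = study

    abundance = pd.concat(blocks, axis=0)
    unclassified = pd.concat(uncl_blocks)
    meta = pd.DataFrame(index=abundance.index) if metadata is None else metadata.reindex(abundance.index).copy()
    meta["study"] = pd.Series(study_of).reindex(abundance.index)
    labels = meta["class"] if "class" in meta.columns else None
    return ProfileDataset(
        abundance=abundance, labels=labels, unclassified=unclassified, metadata=meta
    )


def _drop_into_unclassified(dataset: ProfileDataset, to_drop: list) -> ProfileDataset:
    if not to_drop:
        return dataset
    moved = dataset.abundance[to_drop].sum(axis=1)
    uncl = dataset.unclassified
    uncl = moved if uncl is None else uncl + moved
    return replace(
        dataset,
        abundance=dataset.abundance.drop(columns=to_drop),
        unclassified=uncl,
    )


def filter_low_abundance(
    dataset: ProfileDataset,
    threshold: float = 1.0,
    criterion: str = "max",
) -> ProfileDataset:
    """Remove species whose abundance never (or on average never) reaches ``threshold``.

    With ``criterion="max"`` (default) a species is removed when its
    maximum relative abundance across all samples is below ``threshold``
    percent — the most conservative reading of "relative abundance lower
    than 1%", since a species ever reaching the threshold is kept.
    ``criterion="mean"`` uses the across-sample mean instead.  Removed
    abundance is moved to the unclassified remainder.
    """
    if threshold < 0:
        raise InvalidParameterError(f"threshold must be >= 0, got {threshold}")
    if criterion not in ("max", "mean"):
        raise InvalidParameterError(f"criterion must be 'max' or 'mean', got {criterion!r}")
    stat = dataset.abundance.max(axis=0) if criterion == "max" else dataset.abundance.mean(axis=0)
    to_drop = list(stat.index[stat < threshold])
    return _drop_into_unclassified(dataset, to_drop)


def filter_low_prevalence(dataset: ProfileDataset, min_fraction: float = 0.05) -> ProfileDataset:
    """Remove species detected in strictly fewer than ``min_fraction`` of samples.

    Detection means abundance > 0, mirroring the binarisation rule.  With
    100 samples and the default 5%, a species seen in 4 samples is removed
    and one seen in 5 is kept.  Removed abundance moves to unclassified.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise InvalidParameterError(f"min_fraction must be in [0, 1], got {min_fraction}")
    detected = (dataset.abundance > 0).sum(axis=0)
    cutoff = min_fraction * dataset.n_samples
    to_drop = list(detected.index[detected < cutoff])
    return _drop_into_unclassified(dataset, to_drop)


def binarize(dataset: ProfileDataset) -> ProfileDataset:
    """Presence/absence transform: value -> 1 if > 0 else 0.

    Idempotent.  The unclassified remainder is dropped (presence of
    unassigned reads is not a feature).
    """
    if (dataset.abundance.to_numpy() < 0).any():
        raise InvalidInputError("negative abundance values cannot be binarised")
    binary = (dataset.abundance > 0).astype(np.int64)
    return replace(dataset, abundance=binary, unclassified=None)


def stratify(
    dataset: ProfileDataset,
    by: str = "none",
    age_cutoff: float = 65,
) -> tuple[dict, list]:
    """Split the dataset into strata by sex or age category.

    ``by="sex"`` gives ``{"male": ..., "female": ...}``; ``by="age_category"``
    gives ``{"adult": ...,"senior": ...}`` with adult meaning age <= 65 and
    senior age > 65; ``by="none"`` returns the dataset unchanged under the
    key ``"all"``.  Samples whose stratification value is missing or
    unrecognised are excluded from every stratum and returned as the
    second element.
    """
    if by == "none":
        return {"all": dataset}, []
    if dataset.metadata is None:
        raise InvalidInputError("stratification requires sample metadata")
    if by == "sex":
        sex = dataset.metadata.get("sex")
        if sex is None:
            raise InvalidInputError("metadata has no 'sex' column")
        sex = sex.astype(str).str.lower()
        groups = {
            "male": list(sex.index[sex == "male"]),
            "female": list(sex.index[sex == "female"]),
        }
        excluded = [s for s in dataset.sample_ids if s not in set(groups["male"]) | set(groups["female"])]
    elif by == "age_category":
        age = dataset.metadata.get("age")
        if age is None:
            raise InvalidInputError("metadata has no 'age' column")
        age = pd.to_numeric(age, errors="coerce")
        groups = {
            "adult": list(age.index[age <= age_cutoff]),
            "senior": list(age.index[age > age_cutoff]),
        }
        excluded = list(age.index[age.isna()])
    else:
        raise InvalidParameterError(
            f"unknown stratification key {by!r}; use 'sex', 'age_category' or 'none'"
        )
    strata = {name: dataset.select_samples(ids) for name, ids in groups.items() if ids}
    return strata, excluded
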