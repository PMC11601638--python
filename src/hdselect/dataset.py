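"""In-memory container for microbial profile datasets.

A :class:`ProfileDataset` holds a samples x species abundance matrix (as a
pandas DataFrame), optional class labels, the per-sample ``unclassified``
remainder (abundance MetaPhlAn could not assign to a known species, plus
anything moved there by the preprocessing filters), and optional sample
metadata (class, sex, age, study).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["ProfileDataset"]


@dataclass
class ProfileDataset:
    """Samples x features numeric matrix with labels and metadata.

    Parameters
    ----------
    abundance
        DataFrame indexed by sample id, one column per species; values are
        relative abundances (0-100) or binary presence (0/1).
    labels
        Class label per sample (index-aligned with ``abundance``).  May be
        ``None`` for unlabeled data; training requires labels.
    unclassified
        Per-sample unassigned abundance.  ``None`` after binarisation.
    metadata
        Per-sample table (columns such as ``class``, ``sex``, ``age``,
        ``study``), index-aligned with ``abundance``.
    """

    abundance: pd.DataFrame
    labels: pd.Series | None = None
    unclassified: pd.Series | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.abundance.index.is_unique:
            raise InvalidInputError("sample ids must be unique")
        if not self.abundance.columns.is_unique:
            raise InvalidInputError("feature (species) names must be unique")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.abundance.index)
            if self.labels.isna().any():
                missing = list(self.labels.index[self.labels.isna()])[:3]
                raise InvalidInputError(f"labels missing for samples {missing}")
        if self.unclassified is not None:
            self.unclassified = self.unclassified.reindex(self.abundance.index)
            if self.unclassified.isna().any():
                raise InvalidInputError("unclassified values missing for some samples")
        if self.metadata is not None:
            self.metadata = self.metadata.reindex(self.abundance.index)

    # -- basic views ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)

    @property
    def classes(self) -> list:
        """Distinct class labels in sorted order (the prediction tie-break order)."""
        if self.labels is None:
            return []
        return sorted(self.labels.unique())

    def per_sample_totals(self) -> pd.Series:
        """Species abundance plus unclassified remainder, per sample."""
        totals = self.abundance.sum(axis=1)
        if self.unclassified is not None:
            totals = totals + self.unclassified
        return totals

    # -- subsetting ----------------------------------------------------

    def select_features(self, names: Sequence[str]) -> "ProfileDataset":
        """Dataset restricted to ``names``, in the order given."""
        names = list(names)
        missing = set(names) - set(self.abundance.columns)
        if missing:
            raise InvalidInputError(f"unknown features: {sorted(missing)[:5]}")
        return replace(self, abundance=self.abundance.loc[:, names])

    def select_samples(self, ids: Sequence[str]) -> "ProfileDataset":
        """Dataset restricted to sample ``ids``, in the order given."""
        ids = list(ids)
        missing = set(ids) - set(self.abundance.index)
        if missing:
            raise InvalidInputError(f"unknown samples: {sorted(missing)[:5]}")
        return ProfileDataset(
            abundance=self.abundance.loc[ids],
            labels=None if self.labels is None else self.labels.loc[ids],
            unclassified=None if self.unclassified is None else self.unclassified.loc[ids],
            metadata=None if self.metadata is None else self.metadata.loc[ids],
        )

    def value_range(self) -> tuple[float, float]:
        """Observed (min, max) of the matrix; degenerate ranges are widened by 1."""
        vmin = float(np.nanmin(self.values)) if self.n_features else 0.0
        vmax = float(np.nanmax(self.values)) if self.n_features else 1.0
        if vmax <= vmin:
            vmax = vmin + 1.0
        return vmin, vmax
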