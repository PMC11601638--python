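"""Readers and writers for MetaPhlAn-style abundance tables and metadata.

The abundance dialect: tab-separated, first column clade names, header row
of sample ids, values relative-abundance percent (0-100).  Clade names use
the rank-prefix convention (``k__...|p__...|...|s__Species_name``); only
species-level rows (deepest rank ``s__``) and the ``unclassified`` row are
consumed, everything else is ignored with a log message.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ProfileDataset
from .exceptions import ProfileParseError

__all__ = ["read_profiles", "write_profiles", "read_metadata", "write_metadata"]

log = logging.getLogger(__name__)


def _is_species_row(name: str) -> bool:
    last = name.split("|")[-1]
    return last.startswith("s__")


def read_profiles(path, metadata: pd.DataFrame | None = None) -> ProfileDataset:
    """Read a MetaPhlAn-style TSV into a :class:`ProfileDataset`.

    Samples become rows internally.  Non-species clade rows are skipped.
    A missing ``unclassified`` row is synthesised as ``100 - column sum``
    (floored at 0) with a warning.  Values outside [0, 100] or non-numeric
    cells raise :class:`ProfileParseError`.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed TSV
        raise ProfileParseError(f"cannot parse {path}: {exc}") from exc
    if table.empty:
        raise ProfileParseError(f"{path} has no data rows")

    numeric = table.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & table.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ProfileParseError(
            f"non-numeric value at row {table.index[r]!r}, column {table.columns[c]!r}"
        )
    numeric = numeric.fillna(0.0)
    if (numeric.to_numpy() < 0).any() or (numeric.to_numpy() > 100).any():
        raise ProfileParseError(f"{path}: abundance values must lie in [0, 100]")

    mask_uncl = numeric.index.str.lower().isin(("unclassified", "unknown"))
    species_mask = np.array([_is_species_row(str(i)) for i in numeric.index]) & ~mask_uncl
    skipped = numeric.index[~species_mask & ~mask_uncl]
    if len(skipped):
        log.info("skipping %d non-species rows (e.g. %r)", len(skipped), str(skipped[0]))

    species = numeric.loc[species_mask]
    if mask_uncl.any():
        uncl = numeric.loc[mask_uncl].iloc[0]
    else:
        log.warning("%s: no unclassified row; synthesising as 100 - column sums", path)
        uncl = (100.0 - species.sum(axis=0)).clip(lower=0.0)

    abundance = species.T
    labels = None
    if metadata is not None:
        metadata = metadata.reindex(abundance.index)
        if "class" in metadata.columns:
            labels = metadata["class"]
    return ProfileDataset(
        abundance=abundance, labels=labels, unclassified=uncl, metadata=metadata
    )


def write_profiles(dataset: ProfileDataset, path) -> None:
    """Write a dataset back to the MetaPhlAn-style taxa x samples TSV."""
    path = Path(path)
    table = dataset.abundance.T
    if dataset.unclassified is not None:
        uncl = dataset.unclassified.rename("unclassified")
        table = pd.concat([uncl.to_frame().T, table])
    table.index.name = "clade_name"
    table.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (columns: sample_id, class, sex, age, study)."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ProfileParseError(f"{path}: metadata needs a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        raise ProfileParseError(f"{path}: duplicate sample ids in metadata")
    meta = meta.set_index("sample_id")
    if "age" in meta.columns:
        meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
        if (meta["age"].dropna() < 0).any():
            raise ProfileParseError(f"{path}: negative ages are invalid")
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample_id").to_csv(path, sep="\t")
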