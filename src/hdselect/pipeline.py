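"""End-to-end pipeline binding preprocessing, selection and statistics.

``run_pipeline`` executes one of four modes:

* ``simulate`` — write a synthetic cohort (profiles TSV + metadata TSV +
  ground-truth JSON);
* ``classify`` — preprocess and cross-validate the HD classifier;
* ``select``  — preprocess and run backward variable elimination, writing
  the candidate ledger TSV and a summary JSON;
* ``stats``   — preprocess and write the differential-abundance TSV.

Outputs are deterministic for a fixed config and seed; partially written
artefacts are removed when a stage fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .classifier import cross_validate
from .dataset import ProfileDataset
from .exceptions import HDSelectError, InvalidParameterError
from .io import read_metadata, read_profiles, write_metadata, write_profiles
from .preprocess import (
    binarize,
    filter_low_abundance,
    filter_low_prevalence,
    harmonize_studies,
    stratify,
)
from .selection import SelectionConfig, backward_eliminate, write_ledger, write_summary
from .simulate import SyntheticSpec, generate
from .stats import wilcoxon_bh

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

_MODES = ("simulate", "classify", "select", "stats")


@dataclass
class RunConfig:
    """Configuration mirrored by the command-line flags.

    Defaults are the published operating point: d=10,000 dimensions,
    L=1,000 levels for relative-abundance data (2 for binary), R=10
    retraining passes, 5 folds, 60% accuracy threshold, 1% uncertainty
    band, 70% sub-optimal floor, age split at 65.
    """

    mode: str = "select"
    profiles: tuple = ()
    metadata: str | None = None
    outdir: str = "hdselect_out"
    dimensionality: int = 10_000
    levels: int | None = None
    retrain_iterations: int = 10
    folds: int = 5
    accuracy_threshold: float = 0.60
    uncertainty_pct: float = 1.0
    suboptimal_floor: float = 0.70
    stratify_by: str = "none"
    binary: bool = False
    abundance_threshold: float = 1.0
    prevalence_fraction: float = 0.05
    case_label: str = "CRC"
    control_label: str = "control"
    seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise InvalidParameterError(f"mode must be one of {_MODES}, got {self.mode!r}")

    @property
    def effective_levels(self) -> int:
        if self.levels is not None:
            return self.levels
        return 2 if self.binary else 1_000


def _load(config: RunConfig) -> ProfileDataset:
    meta = read_metadata(config.metadata) if config.metadata else None
    if len(config.profiles) == 1:
        ds = read_profiles(config.profiles[0], metadata=meta)
    else:
        tables = {
            Path(p).stem: pd.read_csv(p, sep="\t", index_col=0) for p in config.profiles
        }
        ds = harmonize_studies(tables, metadata=meta)
    ds = filter_low_abundance(ds, threshold=config.abundance_threshold)
    ds = filter_low_prevalence(ds, min_fraction=config.prevalence_fraction)
    return ds


def _selection_config(config: RunConfig) -> SelectionConfig:
    return SelectionConfig(
        accuracy_threshold=config.accuracy_threshold,
        uncertainty_pct=config.uncertainty_pct,
        suboptimal_floor=config.suboptimal_floor,
        folds=config.folds,
        retrain_iterations=config.retrain_iterations,
        dimensionality=config.dimensionality,
        levels=config.effective_levels,
        seed=config.seed,
        max_workers=config.workers,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured mode; returns a map of artefact name -> path."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        if config.mode == "simulate":
            spec = SyntheticSpec(seed=config.seed)
            ds, informative = generate(spec)
            written["profiles"] = outdir / "profiles.tsv"
            written["metadata"] = outdir / "metadata.tsv"
            written["truth"] = outdir / "truth.json"
            write_profiles(ds, written["profiles"])
            write_metadata(ds.metadata, written["metadata"])
            written["truth"].write_text(
                json.dumps({"informative_species": informative, "seed": config.seed}, indent=2)
                + "\n"
            )
            return {k: str(v) for k, v in written.items()}

        dataset = _load(config)
        strata, excluded = stratify(dataset, by=config.stratify_by)
        if excluded:
            log.info("excluded %d samples lacking the stratification value", len(excluded))

        for name, stratum in strata.items():
            prefix = "" if name == "all" else f"{name}."
            raw_abundance = stratum.abundance.copy()
            if config.binary:
                stratum = binarize(stratum)

            if config.mode == "classify":
                cv = cross_validate(
                    stratum,
                    k=config.folds,
                    d=config.dimensionality,
                    L=config.effective_levels,
                    R=config.retrain_iterations,
                    seed=config.seed,
                )
                out = outdir / f"{prefix}classify.json"
                written[f"{prefix}classify"] = out
                out.write_text(
                    json.dumps(
                        {
                            "mean_accuracy": round(cv.mean_accuracy, 6),
                            "fold_accuracies": [round(a, 6) for a in cv.fold_accuracies],
                            "fold_retrain_iterations": list(cv.fold_retrain_iterations),
                            "seed": config.seed,
                        },
                        indent=2,
                        sort_keys=True,
                    )
                    + "\n"
                )
            elif config.mode == "select":
                result = backward_eliminate(stratum, _selection_config(config))
                ledger = outdir / f"{prefix}selection_ledger.tsv"
                summary = outdir / f"{prefix}selection_summary.json"
                written[f"{prefix}ledger"] = ledger
                written[f"{prefix}summary"] = summary
                write_ledger(result, ledger)
                write_summary(result, summary)
                log.info(
                    "%s: %d models evaluated, %d features selected (seed %d)",
                    name, result.models_evaluated, len(result.selected_features), config.seed,
                )
            elif config.mode == "stats":
                table = wilcoxon_bh(
                    stratum,
                    case_label=config.case_label,
                    control_label=config.control_label,
                    abundance=raw_abundance,
                )
                out = outdir / f"{prefix}diff_stats.tsv"
                written[f"{prefix}stats"] = out
                table.to_csv(out, sep="\t", float_format="%.6g")
        return {k: str(v) for k, v in written.items()}
    except HDSelectError:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
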