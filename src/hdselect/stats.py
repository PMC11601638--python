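"""Differential-abundance statistics for case/control profiles.

For every species: prevalence per class (percent of samples with
abundance > 0), log2 fold change of mean relative abundance
(log2(mean_case / mean_control)), a two-sided Wilcoxon rank-sum test, and
Benjamini-Hochberg adjustment across the tested species family.  A species
is called significant when p <= 0.05 and FDR <= 0.2 (both thresholds
configurable); an absolute-log2FC prefilter can optionally
restrict the family before or after the BH correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dataset import ProfileDataset
from .exceptions import InvalidInputError

__all__ = ["prevalence", "log2fc", "rank_sum_pvalue", "wilcoxon_bh"]

_EXACT_MAX_POOLED = 50


def prevalence(values, mask) -> float:
    """Percent of in-class samples in which the species is present.

    ``values`` is a binary presence column (0/1); ``mask`` selects the
    class.  Returns ``100 * positives / class size``.
    """
    values = np.asarray(values)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise InvalidInputError("prevalence of an empty class is undefined")
    sel = values[mask]
    if not np.isin(sel, (0, 1)).all():
        raise InvalidInputError("prevalence expects binary presence values")
    return 100.0 * float(sel.sum()) / float(mask.sum())


def log2fc(case_values, control_values) -> float:
    """log2 of the ratio of mean case abundance to mean control abundance.

    Degenerate means are flagged through the IEEE result rather than an
    exception: a zero case mean gives ``-inf``, a zero control mean
    ``+inf``, and two zero means ``nan``.
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise InvalidInputError("log2fc needs non-empty case and control groups")
    if (case_values < 0).any() or (control_values < 0).any():
        raise InvalidInputError("abundance values must be non-negative")
    mc, mn = case_values.mean(), control_values.mean()
    if mc == 0.0 and mn == 0.0:
        return float("nan")
    if mc == 0.0:
        return float("-inf")
    if mn == 0.0:
        return float("inf")
    return float(np.log2(mc / mn))


def rank_sum_pvalue(case_values, control_values) -> tuple[float, bool]:
    """Two-sided Wilcoxon rank-sum p-value, with a degeneracy flag.

    Uses the exact null distribution when the pooled sample is small
    (n <= 50) and tie-free, and the normal approximation with tie
    correction otherwise.  A species constant across the pooled samples
    carries no evidence: p is set to 1 and flagged degenerate.
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size < 2 or control_values.size < 2:
        raise InvalidInputError("rank-sum test needs >= 2 samples per class")
    pooled = np.concatenate([case_values, control_values])
    if np.all(pooled == pooled[0]):
        return 1.0, True
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= _EXACT_MAX_POOLED and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(case_values, control_values, alternative="two-sided", method=method)
    return min(1.0, float(res.pvalue)), False


def wilcoxon_bh(
    dataset: ProfileDataset,
    case_label,
    control_label,
    p_thresh: float = 0.05,
    fdr_thresh: float = 0.2,
    abundance: pd.DataFrame | None = None,
    log2fc_min: float | None = None,
    prefilter_before_bh: bool = False,
) -> pd.DataFrame:
    """Per-species differential-abundance table.

    Parameters
    ----------
    dataset
        Profiles with class labels.  Prevalence is computed on presence
        (value > 0); the test and fold change run on the same matrix
        unless ``abundance`` supplies the relative-abundance values (use
        this when selection ran on binarised data).
    case_label, control_label
        Which labels form the case and control groups.
    p_thresh, fdr_thresh
        Significance is the conjunction ``p <= p_thresh`` and
        ``fdr <= fdr_thresh``.
    log2fc_min
        Optional absolute-log2FC filter.  By default it is applied after
        the BH correction (the full tested family is corrected); with
        ``prefilter_before_bh=True`` the family is restricted first and
        species outside it get no FDR and are never significant.

    Returns
    -------
    DataFrame indexed like the feature columns with per-species prevalence
    percentages, log2FC, p-value, FDR, flags and the significance call.
    """
    if dataset.labels is None:
        raise InvalidInputError("differential abundance requires class labels")
    values = dataset.abundance if abundance is None else abundance.reindex(dataset.abundance.index)
    case_mask = (dataset.labels == case_label).to_numpy()
    ctrl_mask = (dataset.labels == control_label).to_numpy()
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise InvalidInputError("need >= 2 samples in both case and control groups")

    rows = []
    for sp in values.columns:
        col = values[sp].to_numpy(dtype=float)
        presence = (col > 0).astype(np.int64)
        p, degenerate = rank_sum_pvalue(col[case_mask], col[ctrl_mask])
        rows.append(
            {
                "species": sp,
                "prevalence_case": prevalence(presence, case_mask),
                "prevalence_control": prevalence(presence, ctrl_mask),
                "log2fc": log2fc(col[case_mask], col[ctrl_mask]),
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows).set_index("species")

    in_family = np.ones(len(table), dtype=bool)
    if log2fc_min is not None and prefilter_before_bh:
        with np.errstate(invalid="ignore"):
            in_family = np.abs(table["log2fc"].to_numpy()) >= log2fc_min
    fdr = np.full(len(table), np.nan)
    if in_family.any():
        fdr[in_family] = multipletests(
            table["p_value"].to_numpy()[in_family], method="fdr_bh"
        )[1]
    table["fdr"] = fdr

    significant = (
        in_family
        & (table["p_value"].to_numpy() <= p_thresh)
        & (np.nan_to_num(fdr, nan=np.inf) <= fdr_thresh)
    )
    if log2fc_min is not None and not prefilter_before_bh:
        with np.errstate(invalid="ignore"):
            significant &= np.abs(table["log2fc"].to_numpy()) >= log2fc_min
    table["significant"] = significant
    return table
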