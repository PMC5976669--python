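"""Tissue- and month-restricted expression calling.

A gene is 'specific' to a condition when its z-score across the condition
panel exceeds 1.5 in exactly that condition and in no other, the standard
single-exceedance rule for multi-tissue TPM panels.  The same rule serves
for a 13-tissue panel and for a 4-month temporal panel.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

Z_THRESHOLD = 1.5


def zscore_profile(row, ddof: int = 1) -> np.ndarray:
    """Standardize one expression row across conditions.

    Sample (n-1) standard deviation by default.  A constant row (sd = 0)
    maps to the all-zero vector: such genes are unclassifiable, not errors.
    """
    x = np.asarray(row, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least two conditions for a z profile")
    sd = x.std(ddof=ddof)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def classify_specific(z, threshold: float = Z_THRESHOLD, labels: Sequence[str] | None = None):
    """Return the unique condition with z > threshold, or None.

    Two or more exceedances mean broad elevation, not specificity.
    """
    z = np.asarray(z, dtype=float)
    hits = np.flatnonzero(z > threshold)
    if hits.size != 1:
        return None
    i = int(hits[0])
    return labels[i] if labels is not None else i


def classify_matrix(tpm: pd.DataFrame, threshold: float = Z_THRESHOLD, ddof: int = 1) -> pd.Series:
    """Specificity label per gene over a conditions panel (None if none)."""
    labels = list(tpm.columns)
    out = [
        classify_specific(zscore_profile(row, ddof=ddof), threshold, labels)
        for row in tpm.to_numpy(dtype=float)
    ]
    return pd.Series(out, index=tpm.index, name="specific_to", dtype=object)


def specificity_table(tpm: pd.DataFrame, threshold: float = Z_THRESHOLD, ddof: int = 1) -> pd.DataFrame:
    """Labels plus the per-condition z-scores, one row per gene."""
    z = np.vstack([zscore_profile(r, ddof=ddof) for r in tpm.to_numpy(dtype=float)])
    tab = pd.DataFrame(z, index=tpm.index, columns=[f"z_{c}" for c in tpm.columns])
    tab.insert(0, "specific_to", classify_matrix(tpm, threshold, ddof))
    return tab


def enrichment_fold(
    spec_in_set: int,
    set_total: int,
    spec_in_background: int,
    background_total: int,
    ndigits: int | None = 1,
) -> float:
    """Fold enrichment of specific genes in a gene set over the background.

    (spec_in_set / set_total) / (spec_in_background / background_total),
    rounded to one decimal by default (pass ndigits=None for the raw ratio).
    """
    if set_total <= 0 or background_total <= 0:
        raise ValidationError("totals must be positive")
    if spec_in_background == 0:
        warnings.warn("zero specific genes in background; enrichment is infinite")
        return np.inf
    fold = (spec_in_set / set_total) / (spec_in_background / background_total)
    return fold if ndigits is None else round(fold, ndigits)


def temporal_ratio_profile(
    expr_case: pd.DataFrame,
    expr_ctrl: pd.DataFrame,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-gene monthly case/control expression ratios.

    Months must match between the two matrices; a small TPM pseudocount
    guards zero denominators.  Aggregate a gene list with
    :func:`aggregate_profile` (mean of per-gene ratios).
    """
    if list(expr_case.columns) != list(expr_ctrl.columns):
        raise ValidationError(
            f"month labels differ: {list(expr_case.columns)} vs {list(expr_ctrl.columns)}"
        )
    common = expr_case.index.intersection(expr_ctrl.index)
    num = expr_case.loc[common].to_numpy(dtype=float) + pseudocount
    den = expr_ctrl.loc[common].to_numpy(dtype=float) + pseudocount
    return pd.DataFrame(num / den, index=common, columns=expr_case.columns)


def aggregate_profile(ratios: pd.DataFrame, gene_ids: Sequence[str] | None = None) -> pd.Series:
    """Mean monthly ratio over a gene list (all genes if None)."""
    sub = ratios if gene_ids is None else ratios.loc[list(gene_ids)]
    return sub.mean(axis=0)


__all__ = [
    "Z_THRESHOLD",
    "aggregate_profile",
    "classify_matrix",
    "classify_specific",
    "enrichment_fold",
    "specificity_table",
    "temporal_ratio_profile",
    "zscore_profile",
]
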