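"""Filtering of imported lncRNA-mRNA and lncRNA-protein interaction tables.

The thermodynamic and statistical predictors themselves (IntaRNA-class
RNA-RNA energy, CatRapid-class RNA-protein strength/power) are inputs, not
reimplemented; this module applies the published acceptance thresholds —
RNA-RNA interaction energy strictly below -100 kcal/mol, RNA-protein
interaction strength and discriminative power of at least 96% — and tests
whether passing pairs are enriched for strong expression correlation.

A toy complementarity-run scorer is included only so the synthetic pipeline
can produce energy-like columns end to end; it is not physical.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .coloc import R_STRONG, chi2_2x2
from .io import ValidationError
from .mirna import normalize_seq, revcomp

ENERGY_THRESHOLD = -100.0
MIN_STRENGTH = 96.0
MIN_POWER = 96.0


def filter_rna_rna(records: pd.DataFrame, energy_threshold: float = ENERGY_THRESHOLD) -> pd.DataFrame:
    """Keep RNA-RNA records with energy strictly below the threshold.

    Exactly -100 kcal/mol is dropped ('< -100' is strict).  Idempotent.
    """
    if "energy" not in records.columns:
        raise ValidationError("RNA-RNA table lacks an 'energy' column")
    energy = records["energy"].to_numpy(dtype=float)
    if np.isnan(energy).any():
        bad = records.index[np.isnan(energy)].tolist()
        raise ValidationError(f"records with missing energy: {bad[:5]}")
    return records.loc[energy < energy_threshold].reset_index(drop=True)


def filter_rna_protein(
    records: pd.DataFrame,
    min_strength: float = MIN_STRENGTH,
    min_power: float = MIN_POWER,
) -> pd.DataFrame:
    """Keep RNA-protein records with strength AND power >= 96% (inclusive)."""
    for col in ("strength", "power"):
        if col not in records.columns:
            raise ValidationError(f"RNA-protein table lacks a {col!r} column")
        v = records[col].to_numpy(dtype=float)
        if np.isnan(v).any() or (v < 0).any() or (v > 100).any():
            raise ValidationError(f"{col} values must be percentages in [0, 100]")
    keep = (records["strength"].to_numpy(dtype=float) >= min_strength) & (
        records["power"].to_numpy(dtype=float) >= min_power
    )
    return records.loc[keep].reset_index(drop=True)


def interaction_correlation_association(
    pass_flags: Sequence[bool],
    pairwise_r: Sequence[float],
    r_thresh: float = R_STRONG,
) -> tuple[float, float]:
    """Chi-square of predicted-interaction status against strong correlation.

    2x2: pass/fail x (|R| handled by caller convention: strong means
    R > r_thresh, matching the transcript-level convention used for
    co-localization enrichment).
    """
    flags = np.asarray(pass_flags, dtype=bool)
    rs = np.asarray(pairwise_r, dtype=float)
    if flags.size != rs.size:
        raise ValidationError("flags and correlations must align")
    strong = rs > r_thresh
    table = np.array(
        [
            [np.sum(flags & strong), np.sum(flags & ~strong)],
            [np.sum(~flags & strong), np.sum(~flags & ~strong)],
        ]
    )
    return chi2_2x2(table)


def toy_interaction_energy(seq_a: str, seq_b: str, per_bp: float = -2.0) -> float:
    """Non-physical stand-in energy from the longest complementary run.

    Scores -2 kcal/mol per base of the longest exact reverse-complement
    stretch shared by the two sequences (found by binary search over
    common k-mers).  Only useful to drive the pipeline's filtering stage on
    synthetic data; bears no relation to real hybridization energies.
    """
    a = normalize_seq(seq_a)
    b = revcomp(seq_b)

    def shares_kmer(k: int) -> bool:
        if k > min(len(a), len(b)) or k == 0:
            return k == 0
        kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
        return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))

    lo, hi = 0, min(len(a), len(b))
    while lo < hi:  # invariant: shares_kmer(lo) is True
        mid = (lo + hi + 1) // 2
        if shares_kmer(mid):
            lo = mid
        else:
            hi = mid - 1
    return per_bp * lo


__all__ = [
    "ENERGY_THRESHOLD",
    "MIN_POWER",
    "MIN_STRENGTH",
    "filter_rna_protein",
    "filter_rna_rna",
    "interaction_correlation_association",
    "toy_interaction_energy",
]
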