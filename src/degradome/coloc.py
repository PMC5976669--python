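"""Genomic co-localization of lncRNA and mRNA loci.

A lncRNA and an mRNA are co-localized when their loci intersect (relation
'overlap', gap 0) or lie on the same chromosome separated by fewer than
``max_dist`` bases between their nearest ends (relation 'neighbor';
'<50 kb' is strict, so a 50,000 bp gap is excluded).  Distances are
strand-agnostic; strand enters only through the sense/antisense orientation
of a pair.  Abutting loci (zero intervening bases) count as 'overlap'.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import TranscriptRecord, ValidationError

MAX_DIST = 50_000
R_STRONG = 0.85


@dataclass(frozen=True)
class ColocPair:
    lncrna: str
    mrna: str
    relation: str  # 'overlap' | 'neighbor'
    gap: int
    orientation: str  # 'sense' | 'antisense'
    pearson_r: float = float("nan")


def _gap(a: TranscriptRecord, b: TranscriptRecord) -> int:
    """Bases strictly between two half-open intervals; negative if they intersect."""
    return max(a.start - b.end, b.start - a.end)


def classify_orientation(strand_lnc: str, strand_mrna: str) -> str:
    """'sense' when the two loci share a strand, 'antisense' otherwise."""
    for s in (strand_lnc, strand_mrna):
        if s not in ("+", "-"):
            raise ValidationError(f"unknown strand {s!r}")
    return "sense" if strand_lnc == strand_mrna else "antisense"


def find_coloc_pairs(
    lnc_records: Iterable[TranscriptRecord],
    mrna_records: Iterable[TranscriptRecord],
    max_dist: int = MAX_DIST,
) -> list[ColocPair]:
    """All overlapping or <max_dist-neighboring lncRNA-mRNA pairs.

    Every qualifying pair is emitted, so one transcript may appear many
    times.  Same-chromosome comparison only; a sorted sweep restricts each
    query to the candidate window.
    """
    by_chrom: dict[str, list[TranscriptRecord]] = {}
    for m in mrna_records:
        by_chrom.setdefault(m.chrom, []).append(m)
    index: dict[str, tuple[list[int], list[TranscriptRecord], int]] = {}
    for chrom, ms in by_chrom.items():
        ms.sort(key=lambda r: (r.start, r.id))
        max_len = max(r.length for r in ms)
        index[chrom] = ([r.start for r in ms], ms, max_len)

    pairs: list[ColocPair] = []
    for lnc in sorted(lnc_records, key=lambda r: (r.chrom, r.start, r.id)):
        if lnc.chrom not in index:
            continue
        starts, ms, max_len = index[lnc.chrom]
        # any partner must start after (lnc.start - max_dist - max_len)
        lo = bisect_left(starts, lnc.start - max_dist - max_len)
        hi = bisect_left(starts, lnc.end + max_dist)
        for m in ms[lo:hi]:
            g = _gap(lnc, m)
            if g <= 0:
                pairs.append(
                    ColocPair(lnc.id, m.id, "overlap", 0, classify_orientation(lnc.strand, m.strand))
                )
            elif g < max_dist:
                pairs.append(
                    ColocPair(lnc.id, m.id, "neighbor", g, classify_orientation(lnc.strand, m.strand))
                )
    return pairs


def pearson_r(x, y) -> float:
    """Pearson correlation; NaN sentinel when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors of at least 3 samples")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def annotate_pairs(pairs: Sequence[ColocPair], expr: pd.DataFrame) -> list[ColocPair]:
    """Attach the expression Pearson R to each pair (rows of ``expr``)."""
    out = []
    for p in pairs:
        for t in (p.lncrna, p.mrna):
            if t not in expr.index:
                raise ValidationError(f"transcript {t} missing from expression matrix")
        r = pearson_r(expr.loc[p.lncrna].to_numpy(), expr.loc[p.mrna].to_numpy())
        out.append(replace(p, pearson_r=r))
    return out


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has an empty margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def correlation_enrichment_test(
    n_strong_coloc: int,
    n_coloc: int,
    n_strong_all: int,
    n_all: int,
    r_thresh: float = R_STRONG,
) -> tuple[float, float]:
    """Are co-localized pairs enriched for strong (R > r_thresh) correlation?

    2x2 chi-square of strong/not-strong x co-localized/all-pairs; the
    ``r_thresh`` argument documents what 'strong' meant for the counts.
    """
    if n_strong_coloc > n_coloc or n_strong_all > n_all:
        raise ValidationError("strong counts exceed their totals")
    table = np.array(
        [[n_strong_coloc, n_coloc - n_strong_coloc], [n_strong_all, n_all - n_strong_all]]
    )
    return chi2_2x2(table)


def orientation_association_test(pairs: Sequence[ColocPair]) -> tuple[float, float]:
    """Chi-square of strand orientation against the sign of expression R."""
    table = np.zeros((2, 2))
    for p in pairs:
        if np.isnan(p.pearson_r):
            continue
        i = 0 if p.orientation == "sense" else 1
        j = 0 if p.pearson_r > 0 else 1
        table[i, j] += 1
    return chi2_2x2(table)


def proximity_correlation(pairs: Sequence[ColocPair]) -> tuple[float, float]:
    """Pearson R (and t-transform p) between gap distance and |expression R|."""
    usable = [p for p in pairs if not np.isnan(p.pearson_r)]
    if len(usable) < 3:
        raise ValidationError("need at least 3 pairs with defined correlation")
    gaps = np.array([p.gap for p in usable], dtype=float)
    mags = np.array([abs(p.pearson_r) for p in usable])
    r, p = stats.pearsonr(gaps, mags)
    return float(r), float(p)


def pairs_to_frame(pairs: Sequence[ColocPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                lncrna=p.lncrna, mrna=p.mrna, relation=p.relation, gap=p.gap,
                orientation=p.orientation, pearson_r=p.pearson_r,
            )
            for p in pairs
        ],
        columns=["lncrna", "mrna", "relation", "gap", "orientation", "pearson_r"],
    )


__all__ = [
    "MAX_DIST",
    "R_STRONG",
    "ColocPair",
    "annotate_pairs",
    "chi2_2x2",
    "classify_orientation",
    "correlation_enrichment_test",
    "find_coloc_pairs",
    "orientation_association_test",
    "pairs_to_frame",
    "pearson_r",
    "proximity_correlation",
]
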