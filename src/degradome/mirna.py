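"""miRNA target-site scanning, consensus calling and sponge detection.

A canonical seed site is a reverse-complement match on the target (read
5'->3') to miRNA positions 2-7 (6mer core).  Extending the match to
position 8 and/or requiring an A opposite position 1 gives the standard
site taxonomy: 8mer, 7mer-m8, 7mer-A1, 6mer.  The built-in scanner is a
deterministic stand-in for external predictors (miRanda/PITA/TargetSpy
class tools), whose imported tables are handled by the consensus and
score-filter operations instead of being recomputed.

mRNAs are scanned in their 3'UTR only; lncRNAs over the full sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coloc import pearson_r
from .io import ValidationError

_COMP = str.maketrans("ACGT", "TGCA")

MIN_ENERGY = -20.0
MIN_SCORE_MIRANDA = 150.0
MIN_SCORE_TARGETSPY = 0.99
SOURCE_SCORE_THRESHOLDS = {"miranda": MIN_SCORE_MIRANDA, "targetspy": MIN_SCORE_TARGETSPY}

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}


def normalize_seq(seq: str) -> str:
    """Uppercase DNA alphabet; RNA input (U) is accepted and mapped to T."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValidationError(f"unexpected characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return normalize_seq(seq).translate(_COMP)[::-1]


@dataclass(frozen=True)
class TargetSite:
    mirna: str
    transcript: str
    region: str  # 'utr3' | 'full'
    start: int  # 0-based half-open, transcript coordinates
    end: int
    site_class: str
    sources: frozenset = frozenset({"seedscan"})
    score: float | None = None
    energy: float | None = None


@dataclass(frozen=True)
class SpongeTriple:
    lncrna: str
    mrna: str
    mirna: str
    r_lnc_mrna: float


# ---------------------------------------------------------------------------
# Seed scanning


def seed_site_string(mirna_seq: str, site_class: str = "8mer") -> str:
    """The target-strand string a site of the given class must match."""
    m = normalize_seq(mirna_seq)
    if len(m) < 8:
        raise ValidationError("miRNA must be at least 8 nt")
    core = revcomp(m[1:7])  # pairs positions 2-7, target 5'->3'
    m8 = revcomp(m[7])  # nucleotide pairing position 8, upstream on target
    if site_class == "8mer":
        return m8 + core + "A"
    if site_class == "7mer-m8":
        return m8 + core
    if site_class == "7mer-A1":
        return core + "A"
    if site_class == "6mer":
        return core
    raise ValidationError(f"unknown site class {site_class!r}")


def scan_seed_sites(
    mirna_seq: str,
    transcript_seq: str,
    mirna_id: str = "mirna",
    transcript_id: str = "transcript",
    region: str = "full",
    utr3: tuple[int, int] | None = None,
) -> list[TargetSite]:
    """All canonical seed sites of one miRNA on one transcript.

    Each 6mer-core match is reported once, upgraded to the most specific
    class supported by the flanking nucleotides; coordinates cover the
    matched site (so an 8mer spans 8 nt).  region='utr3' restricts the scan
    to the annotated 3'UTR interval (transcript coordinates).
    """
    m = normalize_seq(mirna_seq)
    if len(m) < 8:
        raise ValidationError("miRNA must be at least 8 nt")
    t = normalize_seq(transcript_seq)
    if region == "utr3":
        if utr3 is None:
            raise ValidationError(f"{transcript_id}: 3'UTR scan requested but none annotated")
        lo, hi = utr3
    elif region == "full":
        lo, hi = 0, len(t)
    else:
        raise ValidationError(f"unknown region {region!r}")

    core = revcomp(m[1:7])
    m8 = revcomp(m[7])
    sites: list[TargetSite] = []
    j = t.find(core, lo)
    while j != -1 and j + 6 <= hi:
        has_m8 = j - 1 >= lo and t[j - 1] == m8
        has_a1 = j + 6 < hi and t[j + 6] == "A"
        if has_m8 and has_a1:
            cls, s, e = "8mer", j - 1, j + 7
        elif has_m8:
            cls, s, e = "7mer-m8", j - 1, j + 6
        elif has_a1:
            cls, s, e = "7mer-A1", j, j + 7
        else:
            cls, s, e = "6mer", j, j + 6
        sites.append(TargetSite(mirna_id, transcript_id, region, s, e, cls))
        j = t.find(core, j + 1)
    return sites


def scan_transcriptome(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    biotypes: Mapping[str, str],
    utr3s: Mapping[str, tuple[int, int]] | None = None,
    min_class: str | None = None,
) -> list[TargetSite]:
    """Scan every miRNA against every transcript with biotype-aware regions.

    mRNAs are scanned in the 3'UTR (skipped with no UTR annotation),
    lncRNAs full-length; miRNA entries in ``transcripts`` are ignored.
    ``min_class`` keeps only sites at least as specific (e.g. '8mer').
    """
    utr3s = utr3s or {}
    out: list[TargetSite] = []
    for tid, seq in transcripts.items():
        bt = biotypes.get(tid, "mRNA")
        if bt == "miRNA":
            continue
        region = "utr3" if bt == "mRNA" else "full"
        if region == "utr3" and tid not in utr3s:
            continue
        for mid, mseq in mirnas.items():
            out.extend(
                scan_seed_sites(mseq, seq, mid, tid, region, utr3s.get(tid))
            )
    if min_class is not None:
        rank = _CLASS_RANK[min_class]
        out = [s for s in out if _CLASS_RANK[s.site_class] <= rank]
    return out


# ---------------------------------------------------------------------------
# Consensus across prediction sources


def consensus_targets(
    site_sets: Mapping[str, Sequence[TargetSite]],
    k_required: int | None = None,
    exact: bool = False,
) -> list[TargetSite]:
    """Sites supported by >= k_required sources with overlapping coordinates.

    ``k_required`` defaults to all sources (the 'predicted by all 3 tools'
    rule).  A consensus site is the coordinate intersection of one site per
    participating source on the same (miRNA, transcript); with
    ``exact=True`` the coordinates must agree exactly.  Lowering
    ``k_required`` never removes a consensus site (monotone).
    """
    sources = sorted(site_sets)
    if not sources:
        raise ValidationError("need at least one prediction source")
    k = len(sources) if k_required is None else k_required

    grouped: dict[tuple[str, str], dict[str, list[TargetSite]]] = {}
    for src in sources:
        for site in site_sets[src]:
            grouped.setdefault((site.mirna, site.transcript), {}).setdefault(src, []).append(site)

    out: dict[tuple, TargetSite] = {}
    for (mid, tid), per_src in grouped.items():
        avail = sorted(per_src)
        if len(avail) < k:
            continue
        for combo in combinations(avail, k):
            for picks in product(*(per_src[s] for s in combo)):
                if exact:
                    if len({(p.start, p.end) for p in picks}) != 1:
                        continue
                    s, e = picks[0].start, picks[0].end
                else:
                    s = max(p.start for p in picks)
                    e = min(p.end for p in picks)
                    if s >= e:
                        continue
                key = (mid, tid, s, e)
                srcs = frozenset().union(*(p.sources for p in picks))
                if key in out:
                    srcs = srcs | out[key].sources
                out[key] = replace(picks[0], start=s, end=e, sources=srcs)
    return sorted(out.values(), key=lambda x: (x.mirna, x.transcript, x.start, x.end))


def sites_from_frame(df: pd.DataFrame) -> dict[str, list[TargetSite]]:
    """Prediction TSV rows -> per-source TargetSite lists.

    Expected columns: mirna, transcript, start, end, source; optional
    region, score, energy, site_class.
    """
    out: dict[str, list[TargetSite]] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        site = TargetSite(
            mirna=d["mirna"],
            transcript=d["transcript"],
            region=d.get("region", "full"),
            start=int(d["start"]),
            end=int(d["end"]),
            site_class=d.get("site_class", "6mer"),
            sources=frozenset({d["source"]}),
            score=d.get("score"),
            energy=d.get("energy"),
        )
        out.setdefault(d["source"], []).append(site)
    return out


def apply_score_filters(
    predictions: pd.DataFrame,
    min_energy: float = MIN_ENERGY,
    source_thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Filter predictor rows by the per-tool thresholds.

    Keep a row iff its duplex energy passes the common gate
    (energy <= min_energy, default -20 kcal/mol) and its source's score
    threshold, when one is defined (miRanda >= 150, TargetSpy >= 0.99;
    sources without a score threshold are gated by energy alone).
    """
    thresholds = dict(SOURCE_SCORE_THRESHOLDS if source_thresholds is None else source_thresholds)
    if "energy" not in predictions.columns:
        raise ValidationError("prediction table lacks an 'energy' column")
    energy = predictions["energy"].to_numpy(dtype=float)
    if np.isnan(energy).any():
        raise ValidationError("missing energy value in prediction table")
    keep = energy <= min_energy
    for src, thr in thresholds.items():
        mask = predictions["source"].str.lower() == src
        if not mask.any():
            continue
        scores = predictions.loc[mask, "score"].to_numpy(dtype=float)
        if np.isnan(scores).any():
            raise ValidationError(f"missing {src} score in prediction table")
        keep[mask.to_numpy()] &= scores >= thr
    return predictions.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sponges & reciprocal expression


def find_sponge_candidates(
    lnc_sites: Iterable[TargetSite],
    mrna_sites: Iterable[TargetSite],
    expr: pd.DataFrame,
) -> list[SpongeTriple]:
    """(lncRNA, mRNA, miRNA) triples sharing a miRNA, ranked by lnc-mRNA R.

    A triple is emitted for every miRNA with at least one site on the
    lncRNA and one on the mRNA; the Pearson correlation between the two
    transcripts' expression rows annotates the competing-endogenous-RNA
    plausibility of the pair.
    """
    by_mir_lnc: dict[str, set[str]] = {}
    for s in lnc_sites:
        by_mir_lnc.setdefault(s.mirna, set()).add(s.transcript)
    by_mir_mrna: dict[str, set[str]] = {}
    for s in mrna_sites:
        by_mir_mrna.setdefault(s.mirna, set()).add(s.transcript)

    triples: list[SpongeTriple] = []
    for mir in sorted(set(by_mir_lnc) & set(by_mir_mrna)):
        for lnc in sorted(by_mir_lnc[mir]):
            for mr in sorted(by_mir_mrna[mir]):
                for t in (lnc, mr):
                    if t not in expr.index:
                        raise ValidationError(f"transcript {t} missing from expression matrix")
                r = pearson_r(expr.loc[lnc].to_numpy(), expr.loc[mr].to_numpy())
                triples.append(SpongeTriple(lnc, mr, mir, r))
    triples.sort(key=lambda t: (-(t.r_lnc_mrna if not np.isnan(t.r_lnc_mrna) else -2), t.lncrna, t.mrna, t.mirna))
    return triples


def reciprocal_expression_filter(
    de_table: pd.DataFrame, pairs: Iterable[tuple[str, str]]
) -> list[tuple[str, str]]:
    """Keep (miRNA, target) pairs whose DE directions are opposite.

    ``de_table`` is indexed by transcript id with a 'call' column
    (up/down/not-DE); pairs with either member absent or not-DE are dropped.
    """
    calls = de_table["call"]
    kept = []
    for mir, tgt in pairs:
        if mir not in calls.index or tgt not in calls.index:
            continue
        cm, ct = calls[mir], calls[tgt]
        if {cm, ct} == {"up", "down"}:
            kept.append((mir, tgt))
    return kept


# ---------------------------------------------------------------------------
# Pre-miRNA harboring


def find_harbored_premirnas(
    premirna_seqs: Mapping[str, str],
    lncrna_seqs: Mapping[str, str],
) -> list[tuple[str, str, int, str]]:
    """Exact (no mismatch, no gap) pre-miRNA matches inside lncRNA hosts.

    Both strands of the host are searched since annotation strand may
    differ from the mature transcript; every offset is reported as
    (lncrna, premirna, offset on the host's forward sequence, strand).
    A pre-miRNA longer than the host simply yields no hit.
    """
    hits: list[tuple[str, str, int, str]] = []
    for lid, lseq in lncrna_seqs.items():
        host = normalize_seq(lseq)
        for pid, pseq in premirna_seqs.items():
            query = normalize_seq(pseq)
            for strand, q in (("+", query), ("-", revcomp(query))):
                j = host.find(q)
                while j != -1:
                    hits.append((lid, pid, j, strand))
                    j = host.find(q, j + 1)
    hits.sort()
    return hits


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                mirna=s.mirna, transcript=s.transcript, region=s.region,
                start=s.start, end=s.end, site_class=s.site_class,
                sources=",".join(sorted(s.sources)), score=s.score, energy=s.energy,
            )
            for s in sites
        ],
        columns=["mirna", "transcript", "region", "start", "end", "site_class", "sources", "score", "energy"],
    )


def triples_to_frame(triples: Iterable[SpongeTriple]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(lncrna=t.lncrna, mrna=t.mrna, mirna=t.mirna, r_lnc_mrna=t.r_lnc_mrna) for t in triples],
        columns=["lncrna", "mrna", "mirna", "r_lnc_mrna"],
    )


__all__ = [
    "MIN_ENERGY",
    "MIN_SCORE_MIRANDA",
    "MIN_SCORE_TARGETSPY",
    "SITE_CLASSES",
    "SpongeTriple",
    "TargetSite",
    "apply_score_filters",
    "consensus_targets",
    "find_harbored_premirnas",
    "find_sponge_candidates",
    "normalize_seq",
    "reciprocal_expression_filter",
    "revcomp",
    "scan_seed_sites",
    "scan_transcriptome",
    "seed_site_string",
    "sites_from_frame",
    "sites_to_frame",
    "triples_to_frame",
]
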