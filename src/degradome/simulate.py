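"""Self-contained synthetic fixtures emulating the study design.

The generator emits an annotated toy genome (mRNA/lncRNA/miRNA loci with
3'UTR sub-features and controlled lncRNA-mRNA co-localization), transcript
and pre-miRNA sequences with planted canonical seed sites and embedded
64-nt pre-miRNA inserts, a two-group (4 vs 4) negative-binomial count
matrix with planted differential expression at specified fold changes, a
13-tissue TPM panel with planted tissue-restricted genes, a 4-month
temporal panel (one library per month, as in pooled time-point designs),
and a 30-sample panel with planted correlation modules.  Everything planted
is recorded in a GroundTruth object so each downstream stage can be scored
against known structure.

All randomness flows from one integer seed; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, TranscriptRecord, ValidationError
from .mirna import seed_site_string

TISSUES = (
    "red_muscle", "white_muscle", "spleen", "liver", "skin", "testis", "brain",
    "intestine", "stomach", "kidney", "head_kidney", "gill", "fat",
)
MONTHS = ("July", "November", "December", "January")
BASES = "ACGT"

MRNA_LEN = 1500
LNC_LEN = 1000
UTR3_LEN = 300
MIRNA_LEN = 22
PRE_LEN = 64


class SizingError(ValueError):
    """A chromosome is too short for the requested feature load."""


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the design being emulated: 4 replicates per ploidy
    group, 13 tissues, 4 months, 30 co-expression samples, NB dispersion
    0.1 (typical for bulk RNA-seq replicates), planted folds comfortably
    above the |FC| > 3 calling threshold, and ~2x log-uniform library-size
    spread.
    """

    n_mrna: int = 60
    n_lncrna: int = 80
    n_mirna: int = 10
    n_chromosomes: int = 5
    chrom_length: int = 10_000_000
    coloc_fraction: float = 0.3
    de_fraction: float = 0.3
    fold_range: tuple[float, float] = (4.0, 12.0)
    dispersion: float = 0.1
    depth: float = 1_000_000.0
    n_per_group: int = 4
    n_tissues: int = 13
    n_months: int = 4
    n_network_samples: int = 30
    n_modules: int = 2
    module_size: int = 12
    module_loading: float = 0.999
    module_noise_sd: float = 0.01
    lib_size_spread: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_mrna", "n_lncrna", "n_mirna", "n_chromosomes", "chrom_length",
            "n_per_group", "n_tissues", "n_months", "n_network_samples",
            "n_modules", "module_size",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("coloc_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        self.fold_range = tuple(self.fold_range)
        if self.fold_range[0] < 3.0 or self.fold_range[1] < self.fold_range[0]:
            raise ValidationError("fold_range must satisfy 3 <= min <= max")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")
        if self.n_tissues < 2:
            raise ValidationError("n_tissues must be at least 2")


@dataclass
class GroundTruth:
    """Everything planted, verifiable from the emitted files alone."""

    transcripts: dict[str, str] = field(default_factory=dict)  # id -> biotype
    de: dict[str, float] = field(default_factory=dict)  # id -> signed fold
    tissue_specific: dict[str, str] = field(default_factory=dict)
    month_peak: list[str] = field(default_factory=list)  # December-peaking ids
    coloc_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    seed_sites: list[tuple[str, str, int, int]] = field(default_factory=list)
    premirna_hosts: list[tuple[str, str, int]] = field(default_factory=list)
    modules: dict[str, tuple[int, int]] = field(default_factory=dict)  # id -> (module, sign)
    mirna_seqs: dict[str, str] = field(default_factory=dict)
    premirna_seqs: dict[str, str] = field(default_factory=dict)

    def validate(self, records: Sequence[TranscriptRecord], seqs: Mapping[str, str]) -> None:
        ids = {r.id for r in records}
        if set(self.transcripts) != ids:
            raise ValidationError("ground-truth transcript universe differs from annotation")
        planted = (
            set(self.de) | set(self.tissue_specific) | set(self.month_peak)
            | {x for pair in self.coloc_pairs for x in pair[:2]}
            | {t for _, t, _, _ in self.seed_sites}
            | {l for l, _, _ in self.premirna_hosts}
            | set(self.modules)
        )
        missing = planted - ids
        if missing:
            raise ValidationError(f"planted ids absent from annotation: {sorted(missing)[:5]}")
        for mid, tid, s, e in self.seed_sites:
            if not 0 <= s < e <= len(seqs[tid]):
                raise ValidationError(f"planted site {mid}@{tid} outside transcript")
        for lid, pid, off in self.premirna_hosts:
            if seqs[lid][off : off + len(self.premirna_seqs[pid])] != self.premirna_seqs[pid]:
                raise ValidationError(f"planted pre-miRNA {pid} not found in {lid} at {off}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            transcripts=d["transcripts"],
            de=d["de"],
            tissue_specific=d["tissue_specific"],
            month_peak=d["month_peak"],
            coloc_pairs=[tuple(x) for x in d["coloc_pairs"]],
            seed_sites=[tuple(x) for x in d["seed_sites"]],
            premirna_hosts=[tuple(x) for x in d["premirna_hosts"]],
            modules={k: tuple(v) for k, v in d["modules"].items()},
            mirna_seqs=d["mirna_seqs"],
            premirna_seqs=d["premirna_seqs"],
        )


# ---------------------------------------------------------------------------
# Sequence helpers


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(base: str) -> str:
    return BASES[(BASES.index(base) + 1) % 4]


def _scrub_motifs(
    seqs: dict[str, str],
    motifs: Sequence[str],
    planted: Mapping[str, list[tuple[int, int]]],
    protected: Mapping[str, list[tuple[int, int]]],
    max_rounds: int = 50,
) -> None:
    """Mutate away chance occurrences of any motif, in place.

    ``planted`` intervals are legitimate occurrences to keep; ``protected``
    intervals (planted motifs plus pre-miRNA inserts) must not be mutated.
    Iterates to a fixpoint since a mutation can itself spawn a motif.
    """
    def shielded(tid: str) -> list[tuple[int, int]]:
        return planted.get(tid, []) + protected.get(tid, [])

    for _ in range(max_rounds):
        dirty = False
        for tid, seq in seqs.items():
            keep = planted.get(tid, [])
            shield = shielded(tid)
            chars = list(seq)
            for motif in motifs:
                j = seq.find(motif)
                while j != -1:
                    span = (j, j + len(motif))
                    if span not in keep:
                        pos = next(
                            (
                                p
                                for p in range(j + len(motif) // 2, j + len(motif))
                                if not any(a <= p < b for a, b in shield)
                            ),
                            None,
                        )
                        if pos is None:
                            pos = next(
                                p
                                for p in range(j, j + len(motif))
                                if not any(a <= p < b for a, b in shield)
                            )
                        chars[pos] = _mutate(chars[pos])
                        dirty = True
                        seq = "".join(chars)
                    j = seq.find(motif, j + 1)
            seqs[tid] = seq
        if not dirty:
            return
    raise RuntimeError("motif scrubbing did not converge")


# ---------------------------------------------------------------------------
# Genome simulation


def simulate_genome(
    config: SimConfig,
) -> tuple[list[TranscriptRecord], dict[str, str], GroundTruth]:
    """Annotation, transcript sequences and ground truth for a toy genome.

    Co-localized lncRNAs sit within 50 kb of (or overlapping) a partner
    mRNA; all other lncRNAs are at least 200 kb from every mRNA.  Every
    mRNA carries a 3'UTR.  Planted 8mer seed sites are exact
    reverse-complement matches to miRNA positions 2-8 with an A opposite
    position 1, and are the only occurrences of those 8-nt site strings in
    the transcriptome (chance occurrences are scrubbed).  Planted
    pre-miRNAs are exact 64-nt substrings of their host lncRNA.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    # --- miRNAs and pre-miRNAs -------------------------------------------
    mirna_ids = [f"mir-{i+1:03d}" for i in range(config.n_mirna)]
    motifs: list[str] = []
    for mid in mirna_ids:
        seq = _rand_seq(rng, MIRNA_LEN)
        truth.mirna_seqs[mid] = seq
        motifs.append(seed_site_string(seq, "8mer"))
    pre_ids = [f"pre-{m}" for m in mirna_ids]
    for mid, pid in zip(mirna_ids, pre_ids):
        while True:
            pre = _rand_seq(rng, 8) + truth.mirna_seqs[mid] + _rand_seq(rng, PRE_LEN - 8 - MIRNA_LEN)
            if not any(m in pre for m in motifs):
                break
        truth.premirna_seqs[pid] = pre

    # --- genomic layout ---------------------------------------------------
    n_coloc = round(config.coloc_fraction * config.n_lncrna)
    mrna_ids = [f"mrna-{i+1:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"lnc-{i+1:04d}" for i in range(config.n_lncrna)]
    coloc_lnc = lnc_ids[:n_coloc]
    lone_lnc = lnc_ids[n_coloc:]
    partner = {l: mrna_ids[int(rng.integers(0, config.n_mrna))] for l in coloc_lnc}

    blocks: list[tuple[str, list[str]]] = [
        (m, [l for l in coloc_lnc if partner[l] == m]) for m in mrna_ids
    ]
    blocks += [("", [l]) for l in lone_lnc]
    order = rng.permutation(len(blocks))

    records: list[TranscriptRecord] = []
    cursors = {f"chr{c+1}": 0 for c in range(config.n_chromosomes)}
    chrom_names = list(cursors)

    def place(chrom: str, tid: str, biotype: str, start: int, length: int, strand: str,
              utr: bool = False) -> TranscriptRecord:
        end = start + length
        if end > config.chrom_length:
            raise SizingError(
                f"{chrom} too short ({config.chrom_length} bp) to place {tid}; "
                "increase chrom_length or n_chromosomes"
            )
        utr3 = None
        if utr:
            utr3 = (end - UTR3_LEN, end) if strand == "+" else (start, start + UTR3_LEN)
        rec = TranscriptRecord(tid, biotype, chrom, strand, start, end, utr3)
        records.append(rec)
        return rec

    for k, bi in enumerate(order):
        mid, lncs = blocks[bi]
        chrom = chrom_names[k % config.n_chromosomes]
        start = cursors[chrom]
        block_end = start
        if mid:
            strand = "+" if rng.random() < 0.5 else "-"
            m = place(chrom, mid, "mRNA", start, MRNA_LEN, strand, utr=True)
            block_end = m.end
            for l in lncs:
                ls = "+" if rng.random() < 0.5 else "-"
                if rng.random() < 0.2:  # overlapping partner
                    rec = place(chrom, l, "lncRNA", m.start + 200, LNC_LEN, ls)
                    truth.coloc_pairs.append((l, mid, "overlap"))
                else:
                    gap = int(rng.integers(500, 45_000))
                    rec = place(chrom, l, "lncRNA", m.end + gap, LNC_LEN, ls)
                    truth.coloc_pairs.append((l, mid, "neighbor"))
                block_end = max(block_end, rec.end)
        else:
            ls = "+" if rng.random() < 0.5 else "-"
            rec = place(chrom, lncs[0], "lncRNA", start, LNC_LEN, ls)
            block_end = rec.end
        cursors[chrom] = block_end + 200_000 + int(rng.integers(0, 50_000))

    # pre-miRNA loci on the genome (placed after the blocks, far from mRNAs)
    for pid in pre_ids:
        chrom = chrom_names[int(rng.integers(0, config.n_chromosomes))]
        start = cursors[chrom]
        rec = place(chrom, pid, "miRNA", start, PRE_LEN, "+")
        cursors[chrom] = rec.end + 200_000

    # --- transcript sequences --------------------------------------------
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.biotype == "miRNA":
            seqs[rec.id] = truth.premirna_seqs[rec.id]
        else:
            seqs[rec.id] = _rand_seq(rng, rec.length)
    truth.transcripts = {rec.id: rec.biotype for rec in records}

    # --- plant pre-miRNA inserts into host lncRNAs ------------------------
    protected: dict[str, list[tuple[int, int]]] = {}
    n_hosts = min(2, config.n_mirna, len(lnc_ids))
    host_lncs = [lnc_ids[-(i + 1)] for i in range(n_hosts)]
    for host, pid in zip(host_lncs, pre_ids[:n_hosts]):
        off = int(rng.integers(0, len(seqs[host]) - PRE_LEN + 1))
        seqs[host] = seqs[host][:off] + truth.premirna_seqs[pid] + seqs[host][off + PRE_LEN:]
        truth.premirna_hosts.append((host, pid, off))
        protected.setdefault(host, []).append((off, off + PRE_LEN))

    # --- plant 8mer seed sites -------------------------------------------
    planted: dict[str, list[tuple[int, int]]] = {}

    def plant(tid: str, mid: str, lo: int, hi: int) -> None:
        motif = seed_site_string(truth.mirna_seqs[mid], "8mer")
        for _ in range(200):
            pos = int(rng.integers(lo, hi - len(motif) + 1))
            span = (pos, pos + len(motif))
            clashes = planted.get(tid, []) + protected.get(tid, [])
            if not any(a < span[1] and span[0] < b for a, b in clashes):
                break
        else:  # pragma: no cover - tiny transcripts only
            raise SizingError(f"no room to plant a site in {tid}")
        seqs[tid] = seqs[tid][: span[0]] + motif + seqs[tid][span[1]:]
        planted.setdefault(tid, []).append(span)
        truth.seed_sites.append((mid, tid, span[0], span[1]))

    n_site_mirnas = min(config.n_mirna, 5)
    for i in range(n_site_mirnas):
        mid = mirna_ids[i]
        target_mrna = mrna_ids[i % config.n_mrna]
        L = len(seqs[target_mrna])
        plant(target_mrna, mid, L - UTR3_LEN, L)  # inside the 3'UTR
        for j in range(2):  # two lncRNA sponges per miRNA
            lnc = lnc_ids[(2 * i + j) % max(1, len(lnc_ids) - n_hosts)]
            plant(lnc, mid, 0, len(seqs[lnc]))

    # remove chance copies of every planted-site string (junctions included)
    _scrub_motifs(seqs, motifs, planted, protected)

    # --- planted DE, tissue specificity, months, modules ------------------
    coding_ids = mrna_ids + lnc_ids
    all_ids = coding_ids + pre_ids
    n_de = round(config.de_fraction * len(all_ids))
    de_ids = [all_ids[int(i)] for i in rng.choice(len(all_ids), size=n_de, replace=False)]
    lo, hi = config.fold_range
    for tid in sorted(de_ids):
        fold = float(rng.uniform(lo, hi))
        truth.de[tid] = fold if rng.random() < 0.5 else -fold

    n_spec = max(2, len(coding_ids) // 5)
    spec_ids = sorted(coding_ids[int(i)] for i in rng.choice(len(coding_ids), size=n_spec, replace=False))
    for tid in spec_ids:
        truth.tissue_specific[tid] = TISSUES[int(rng.integers(0, config.n_tissues))]

    truth.month_peak = sorted(
        coding_ids[int(i)] for i in rng.choice(len(coding_ids), size=max(2, n_spec // 2), replace=False)
    )

    pool = [t for t in all_ids if t not in truth.premirna_seqs]
    picks = rng.choice(len(pool), size=min(config.n_modules * config.module_size, len(pool)), replace=False)
    for k, i in enumerate(picks):
        # sign-pure modules: a shared per-sample scaling constant (depth
        # normalization) adds common-mode variation that caps attainable
        # anti-correlation, so planted anti-members cannot hold |R| > 0.99
        truth.modules[pool[int(i)]] = (k // config.module_size, 1)

    truth.validate(records, seqs)
    return records, seqs, truth


# ---------------------------------------------------------------------------
# Counts


def nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, Var = mu + phi mu^2) sample; Poisson when phi = 0."""
    if phi < 0:
        raise ValidationError("dispersion must be non-negative")
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-300)))


def simulate_two_group_counts(
    n_genes: int,
    n_per_group: int = 4,
    depth: float = 1e6,
    phi: float = 0.1,
    folds: Mapping[int, float] | None = None,
    lib_size_spread: float = 2.0,
    rng: np.random.Generator | None = None,
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generic planted-fold two-group NB count matrix.

    ``folds`` maps gene index -> signed fold (case over control; negative
    means down in the case group); unlisted genes are null.  Group-mean
    ratios equal the planted folds exactly before the per-library depth
    renormalization.  Library sizes are log-uniform over a
    ``lib_size_spread`` x range around ``depth``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    ids = list(gene_ids) if gene_ids is not None else [f"g{i+1:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    ratio = np.ones(n_genes)
    for i, f in (folds or {}).items():
        ratio[i] = f if f > 0 else 1.0 / abs(f)

    half = np.sqrt(lib_size_spread)
    n_tot = 2 * n_per_group
    libs = depth * np.exp(rng.uniform(np.log(1 / half), np.log(half), size=n_tot))
    p_ctrl = base / base.sum()
    p_case = base * ratio / (base * ratio).sum()
    cols, names, groups = [], [], {}
    for j in range(n_per_group):
        name = f"A{j+1}"
        cols.append(nb_draw(rng, p_ctrl * libs[j], phi))
        names.append(name)
        groups[name] = "A"
    for j in range(n_per_group):
        name = f"B{j+1}"
        cols.append(nb_draw(rng, p_case * libs[n_per_group + j], phi))
        names.append(name)
        groups[name] = "B"
    counts = pd.DataFrame(np.column_stack(cols), index=ids, columns=names)
    return counts, groups


def simulate_counts(truth: GroundTruth, config: SimConfig) -> ExpressionMatrix:
    """Two-group counts over the simulated transcriptome.

    Group '2N' is the case (gravid) group carrying the planted folds;
    '3N' is the control.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = sorted(truth.transcripts)
    folds = {ids.index(t): f for t, f in truth.de.items()}
    counts, groups = simulate_two_group_counts(
        len(ids),
        n_per_group=config.n_per_group,
        depth=config.depth,
        phi=config.dispersion,
        folds=folds,
        lib_size_spread=config.lib_size_spread,
        rng=rng,
        gene_ids=ids,
    )
    counts.columns = [c.replace("A", "3N_").replace("B", "2N_") for c in counts.columns]
    groups = {c: ("3N" if c.startswith("3N") else "2N") for c in counts.columns}
    return ExpressionMatrix(counts, unit="count", groups=groups)


# ---------------------------------------------------------------------------
# Panels


def simulate_panels(
    truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(tissue TPM, month 2N, month 3N, 30-sample network matrix).

    Tissue-specific ids get a 20x elevated mean in exactly their tissue;
    December-peaking genes rise 6x in the case (2N) month series only;
    module members load on a shared latent factor with |R| near 1 inside a
    module (sign -1 members anti-correlate); everything else is independent
    noise.
    """
    if config.n_tissues < 2:
        raise ValidationError("n_tissues must be at least 2")
    rng = np.random.default_rng(config.seed + 2)
    ids = sorted(truth.transcripts)
    tissues = list(TISSUES[: config.n_tissues])
    months = list(MONTHS[: config.n_months])

    base = rng.lognormal(mean=1.0, sigma=0.8, size=len(ids))

    tissue = base[:, None] * rng.lognormal(0.0, 0.2, size=(len(ids), len(tissues)))
    for i, tid in enumerate(ids):
        t = truth.tissue_specific.get(tid)
        if t is not None and t in tissues:
            tissue[i, tissues.index(t)] *= 20.0
    tissue_df = pd.DataFrame(tissue, index=ids, columns=tissues)

    m2 = base[:, None] * rng.lognormal(0.0, 0.1, size=(len(ids), len(months)))
    m3 = base[:, None] * rng.lognormal(0.0, 0.1, size=(len(ids), len(months)))
    dec = months.index("December") if "December" in months else len(months) - 1
    for i, tid in enumerate(ids):
        if tid in set(truth.month_peak):
            m2[i, dec] *= 6.0
    month2_df = pd.DataFrame(m2, index=ids, columns=months)
    month3_df = pd.DataFrame(m3, index=ids, columns=months)

    n = config.n_network_samples
    factors = rng.standard_normal(size=(config.n_modules, n))
    net = np.empty((len(ids), n))
    for i, tid in enumerate(ids):
        eps = rng.standard_normal(n)
        if tid in truth.modules:
            mod, sign = truth.modules[tid]
            latent = sign * (config.module_loading * factors[mod] + config.module_noise_sd * eps)
        else:
            latent = eps
        net[i] = np.maximum(base[i] * (1.0 + 0.15 * latent), 0.0)
    network_df = pd.DataFrame(net, index=ids, columns=[f"s{j+1:02d}" for j in range(n)])

    return tissue_df, month2_df, month3_df, network_df


def transcript_utr3s(seqs: Mapping[str, str], biotypes: Mapping[str, str]) -> dict[str, tuple[int, int]]:
    """Transcript-coordinate 3'UTR intervals: the last UTR3_LEN nt of each mRNA."""
    return {
        tid: (len(seq) - UTR3_LEN, len(seq))
        for tid, seq in seqs.items()
        if biotypes.get(tid) == "mRNA" and len(seq) > UTR3_LEN
    }


__all__ = [
    "GroundTruth",
    "MONTHS",
    "SimConfig",
    "SizingError",
    "TISSUES",
    "nb_draw",
    "simulate_counts",
    "simulate_genome",
    "simulate_panels",
    "simulate_two_group_counts",
    "transcript_utr3s",
]
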