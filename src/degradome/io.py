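"""Domain containers and flat-file readers/writers.

Coordinates are 0-based half-open in memory; GFF3 is written 1-based
inclusive and BED 0-based half-open, per the two formats' conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BIOTYPES = ("mRNA", "lncRNA", "miRNA")
_GFF_TYPE = {"mRNA": "mRNA", "lncRNA": "lnc_RNA", "miRNA": "pre_miRNA"}
_GFF_TYPE_REV = {v: k for k, v in _GFF_TYPE.items()}


class ValidationError(ValueError):
    """Raised when a record or table violates a documented contract."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A genomic feature: locus interval plus optional 3'UTR sub-interval."""

    id: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.id}: unknown biotype {self.biotype!r}")
        if not self.chrom:
            raise ValidationError(f"{self.id}: empty chromosome")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.id}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise ValidationError(
                f"{self.id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.utr3 is not None:
            u0, u1 = self.utr3
            if not (self.start <= u0 < u1 <= self.end):
                raise ValidationError(f"{self.id}: utr3 {self.utr3} outside locus")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionMatrix:
    """Transcripts x samples table with a unit tag and optional group labels."""

    values: pd.DataFrame
    unit: str = "count"
    groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("count", "TPM"):
            raise ValidationError(f"unit must be 'count' or 'TPM', got {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.groups is not None:
            missing = set(self.values.columns) - set(self.groups)
            if missing:
                raise ValidationError(f"samples without group label: {sorted(missing)}")

    @property
    def transcripts(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# TSV matrices


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a transcripts x samples matrix (first column = transcript id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript")


def read_lengths_tsv(path: str | Path) -> dict[str, int]:
    """Two-column TSV: transcript id, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "length"])
    return dict(zip(df["id"], df["length"].astype(int)))


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample id, group label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return dict(zip(df["sample"], df["group"]))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 / BED annotation

_SOURCE = "degradome"


def write_gff3(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """1-based inclusive coordinates; 3'UTRs as three_prime_UTR children."""
    lines = ["##gff-version 3"]
    for rec in records:
        attrs = f"ID={rec.id};biotype={rec.biotype}"
        lines.append(
            "\t".join(
                [
                    rec.chrom,
                    _SOURCE,
                    _GFF_TYPE[rec.biotype],
                    str(rec.start + 1),
                    str(rec.end),
                    ".",
                    rec.strand,
                    ".",
                    attrs,
                ]
            )
        )
        if rec.utr3 is not None:
            u0, u1 = rec.utr3
            lines.append(
                "\t".join(
                    [
                        rec.chrom,
                        _SOURCE,
                        "three_prime_UTR",
                        str(u0 + 1),
                        str(u1),
                        ".",
                        rec.strand,
                        ".",
                        f"ID={rec.id}.utr3;Parent={rec.id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[TranscriptRecord]:
    parents: dict[str, dict] = {}
    utrs: dict[str, tuple[int, int]] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, _score, strand, _frame, attrs = line.split("\t")
        fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "three_prime_UTR":
            utrs[fields["Parent"]] = (int(start) - 1, int(end))
        elif ftype in _GFF_TYPE_REV:
            rid = fields["ID"]
            parents[rid] = dict(
                id=rid,
                biotype=fields.get("biotype", _GFF_TYPE_REV[ftype]),
                chrom=chrom,
                strand=strand,
                start=int(start) - 1,
                end=int(end),
            )
            order.append(rid)
    return [TranscriptRecord(**parents[rid], utr3=utrs.get(rid)) for rid in order]


def write_bed(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """BED6, 0-based half-open (main intervals only; UTRs are GFF3-only)."""
    lines = [
        "\t".join([r.chrom, str(r.start), str(r.end), r.id, "0", r.strand])
        for r in records
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path, biotypes: Mapping[str, str] | None = None) -> list[TranscriptRecord]:
    """BED6 reader; biotype taken from the optional id->biotype map, else mRNA."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, end, name, _score, strand = line.split("\t")[:6]
        bt = biotypes.get(name, "mRNA") if biotypes else "mRNA"
        out.append(
            TranscriptRecord(
                id=name, biotype=bt, chrom=chrom, strand=strand,
                start=int(start), end=int(end),
            )
        )
    return out


__all__ = [
    "BIOTYPES",
    "ExpressionMatrix",
    "TranscriptRecord",
    "ValidationError",
    "read_bed",
    "read_fasta",
    "read_gff3",
    "read_groups_tsv",
    "read_lengths_tsv",
    "read_matrix_tsv",
    "write_bed",
    "write_fasta",
    "write_gff3",
    "write_matrix_tsv",
]
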