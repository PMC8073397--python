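"""Genome/interval containers and the file formats every pipeline stage touches.

Coordinate contract
-------------------
All *reported* coordinates are 1-based inclusive on the forward strand, the
GenBank convention used throughout plant-mitogenome literature (so a reverse
gene printed as ``259,955-260,893`` keeps exactly those numbers).  Internal
arithmetic is 0-based half-open; :class:`Interval` owns the single conversion
layer.  Circular genomes are stored linearised at an arbitrary origin; an
interval that wraps the origin has ``end < start`` and length
``(L - start + 1) + end``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "Genome",
    "Interval",
    "Feature",
    "read_fasta",
    "write_fasta",
    "read_allele_counts",
    "write_feature_table",
]

VALID_NT = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files (FASTA, allele-count TSV)."""


@dataclass(frozen=True)
class Genome:
    """A nucleotide sequence with identifier.

    ``seq`` is uppercase over {A,C,G,T,N}; circular genomes are linearised at
    an arbitrary origin and all interval math honours wrap-around.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_NT
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"genome {self.id!r}: illegal character {self.seq[pos]!r} "
                f"at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, iv: "Interval") -> str:
        """Forward-strand sequence under ``iv`` (wrap-aware; strand ignored)."""
        pieces = iv.to_slices(len(self.seq))
        return "".join(self.seq[a:b] for a, b in pieces)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval; ``end < start`` means wrap on a circle."""

    start: int
    end: int
    strand: int = 1

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"positions must be >= 1, got {self.start}..{self.end}")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("wrapping interval needs the genome length")
        return (genome_length - self.start + 1) + self.end

    def to_slices(self, genome_length: int) -> list[tuple[int, int]]:
        """0-based half-open pieces on the linearised sequence."""
        if not self.wraps:
            return [(self.start - 1, self.end)]
        return [(self.start - 1, genome_length), (0, self.end)]

    def positions(self, genome_length: int) -> Iterable[int]:
        """All 0-based positions covered, in order."""
        for a, b in self.to_slices(genome_length):
            yield from range(a, b)

    def overlaps(self, other: "Interval", genome_length: int) -> bool:
        """Wrap-aware: true iff the two intervals share >= 1 position."""
        mine = _piece_set(self, genome_length)
        theirs = _piece_set(other, genome_length)
        for a, b in mine:
            for c, d in theirs:
                if a < d and c < b:
                    return True
        return False


def _piece_set(iv: Interval, L: int) -> list[tuple[int, int]]:
    return iv.to_slices(L)


@dataclass(frozen=True)
class Feature:
    """A labelled interval for the feature-table output."""

    id: str
    interval: Interval
    type: str = "misc"
    attributes: str = ""


def read_fasta(path: str | Path, circular: bool = False) -> list[Genome]:
    """Read a (multi-)FASTA into :class:`Genome` records, order preserved.

    Sequences are uppercased, U is mapped to T, and any character outside
    {A,C,G,T,N} raises :class:`FormatError` naming its position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    genomes: list[Genome] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        seq = re.sub(r"\s", "", seq)
        bad = set(seq) - VALID_NT
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise FormatError(
                f"{path}: record {rec.id!r} has illegal character "
                f"{seq[pos]!r} at position {pos + 1}"
            )
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} is empty")
        genomes.append(Genome(id=rec.id, seq=seq, circular=circular))
    return genomes


def write_fasta(genomes: Sequence[Genome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


ALLELE_COLUMNS = ["chrom", "pos", "ref_count_bulk1", "alt_count_bulk1",
                  "ref_count_bulk2", "alt_count_bulk2"]


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-SNP allele-count TSV (one row per site, two bulks).

    Returns a typed DataFrame with the six required columns plus a boolean
    ``zero_depth`` flag marking rows where either bulk has total depth 0
    (retained, not dropped).  Positions must be strictly increasing within
    each chromosome and counts non-negative.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[ALLELE_COLUMNS].copy()
    count_cols = ALLELE_COLUMNS[2:]
    for c in ["pos"] + count_cols:
        df[c] = pd.to_numeric(df[c], errors="raise").astype(int)
    if (df[count_cols] < 0).any().any():
        raise FormatError(f"{path}: negative allele count")
    for chrom, sub in df.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
            raise FormatError(f"{path}: positions not strictly increasing on {chrom}")
    df["zero_depth"] = (
        (df.ref_count_bulk1 + df.alt_count_bulk1 == 0)
        | (df.ref_count_bulk2 + df.alt_count_bulk2 == 0)
    )
    return df


def write_feature_table(features: Sequence[Feature], path: str | Path) -> None:
    """Write features as TSV with stable ordering by (start, end, id)."""
    rows = sorted(features, key=lambda f: (f.interval.start, f.interval.end, f.id))
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\tstrand\ttype\tattributes\n")
        for f in rows:
            strand = "+" if f.interval.strand == 1 else "-"
            fh.write(
                f"{f.id}\t{f.interval.start}\t{f.interval.end}\t{strand}\t"
                f"{f.type}\t{f.attributes}\n"
            )
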