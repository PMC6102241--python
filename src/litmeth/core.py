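"""Core genomic value types shared by every stage of the pipeline.

All coordinates are 0-based, half-open (BED convention) internally;
conversion to and from 1-based formats (GTF, RepeatMasker .out) happens
only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: RepeatMasker class/family token -> internal LTR class.
LTR_CLASS_MAP = {
    "ERV1": "LTR-ERV1",
    "ERVK": "LTR-ERVK",
    "ERVL": "LTR-ERVL",
    "ERVL-MaLR": "LTR-MaLR",
    "MaLR": "LTR-MaLR",
}

#: Classes counted as potential LIT-initiating elements (LTRs and
#: ERV-internal sequence both qualify).
LTR_CLASSES = frozenset(LTR_CLASS_MAP.values())


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class FormatError(ValueError):
    """Raised when a file does not follow its declared grammar."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end {self.end} must exceed start {self.start}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class RepeatElement:
    """An annotated repeat copy (RepeatMasker row or BED equivalent)."""

    location: GenomicInterval
    repeat_class: str
    subfamily: str
    annotation_source: str = ""

    @property
    def is_ltr(self) -> bool:
        return self.repeat_class in LTR_CLASSES


@dataclass(frozen=True)
class Transcript:
    """An assembled or annotated transcript model.

    Exons are stored in transcription order (5'->3'): ascending genomic
    coordinates on '+', descending on '-'.
    """

    id: str
    location: GenomicInterval
    exons: tuple
    fpkm: float = 0.0
    gene_id: str | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"transcript {self.id} has no exons")
        if self.fpkm < 0:
            raise ValidationError(f"transcript {self.id} has negative FPKM")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValidationError(f"transcript {self.id} has overlapping exons")

    @property
    def strand(self) -> str:
        return self.location.strand

    @property
    def tss(self) -> int:
        """Strand-aware 5' base position (0-based)."""
        if self.strand == "-":
            return self.location.end - 1
        return self.location.start

    @property
    def tts(self) -> int:
        """Strand-aware 3' base position (0-based)."""
        if self.strand == "-":
            return self.location.start
        return self.location.end - 1

    @property
    def first_exon(self) -> GenomicInterval:
        return self.exons[0]


@dataclass(frozen=True)
class ChainAlignment:
    """One UCSC chain: colinear gapped alignment between two genomes.

    ``blocks`` are (source_offset, target_offset, length) triples giving
    ungapped aligned runs, offsets relative to the chain's interval starts.
    Only forward-strand chains are supported; reversed blocks are rejected
    at parse time.
    """

    source_interval: GenomicInterval
    target_interval: GenomicInterval
    blocks: tuple
    chain_id: str = ""
    score: float = 0.0

    def __post_init__(self):
        s_prev = t_prev = -1
        for s_off, t_off, ln in self.blocks:
            if ln <= 0:
                raise FormatError(f"chain {self.chain_id}: non-positive block length")
            if s_off < s_prev or t_off < t_prev:
                raise FormatError(f"chain {self.chain_id}: blocks out of order")
            if s_off + ln > self.source_interval.length:
                raise FormatError(f"chain {self.chain_id}: block overflows source span")
            if t_off + ln > self.target_interval.length:
                raise FormatError(f"chain {self.chain_id}: block overflows target span")
            s_prev, t_prev = s_off + ln, t_off + ln


class MethTable:
    """Per-CpG methylation evidence, sorted by (chrom, start).

    Backed by a DataFrame with columns chrom, start, end, meth, total.
    """

    COLUMNS = ("chrom", "start", "end", "meth", "total")

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, list(self.COLUMNS)].copy()
        if len(df):
            bad = df["meth"] > df["total"]
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                row = df.iloc[i]
                raise ValidationError(
                    f"meth count {row.meth} exceeds total {row.total} "
                    f"at {row.chrom}:{row.start}"
                )
            if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
                raise ValidationError("invalid CpG coordinates")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self.df = df

    @classmethod
    def empty(cls) -> "MethTable":
        return cls(pd.DataFrame({c: [] for c in cls.COLUMNS}).astype(
            {"chrom": str, "start": int, "end": int, "meth": int, "total": int}))

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "MethTable":
        rows = list(records)
        if not rows:
            return cls.empty()
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    def chroms(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def fraction(self) -> pd.Series:
        """Per-CpG fractional methylation; NaN where total is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.df["meth"] / self.df["total"]
        return f.where(self.df["total"] > 0)

    def mean_over(self, iv: GenomicInterval, min_depth: int = 1,
                  min_cpgs: int = 1) -> float:
        """Unweighted mean per-CpG methylation over ``iv``.

        Returns NaN when fewer than ``min_cpgs`` CpGs reach ``min_depth``
        (the coverage rule applied throughout region-level summaries).
        """
        sub = self.df[(self.df["chrom"] == iv.chrom)
                      & (self.df["start"] < iv.end)
                      & (self.df["start"] >= iv.start)]
        sub = sub[sub["total"] >= min_depth]
        if len(sub) < min_cpgs:
            return float("nan")
        return float((sub["meth"] / sub["total"]).mean())


def merge_dyads(df: pd.DataFrame) -> pd.DataFrame:
    """Sum plus/minus strand calls at a CpG dyad into one record.

    A record at position p+1 is folded into its predecessor at p on the
    same chromosome (the two strands of one CpG). Idempotent: merged
    records are never at adjacent positions, so a second pass is a no-op.
    """
    if not len(df):
        return df
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    chrom = df["chrom"].to_numpy()
    start = df["start"].to_numpy()
    n = len(df)
    group = np.empty(n, dtype=int)
    head = np.empty(n, dtype=bool)
    gid = -1
    for i in range(n):
        if (i > 0 and head[i - 1] and chrom[i] == chrom[i - 1]
                and start[i] == start[i - 1] + 1):
            group[i] = gid  # second strand of the dyad headed by i-1
            head[i] = False
        else:
            gid += 1
            group[i] = gid
            head[i] = True
    out = (
        df.assign(_g=group)
        .groupby("_g", sort=True)
        .agg(chrom=("chrom", "first"), start=("start", "first"),
             end=("end", "max"), meth=("meth", "sum"), total=("total", "sum"))
        .reset_index(drop=True)
    )
    # widen merged dyads to width 2
    out["end"] = np.maximum(out["end"], out["start"] + 1)
    return out


def build_interval_index(items: Sequence, key=lambda x: x):
    """chrom -> IntervalTree over ``items`` (via interval accessor ``key``)."""
    from intervaltree import IntervalTree

    trees: dict = {}
    for item in items:
        iv = key(item)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, item)
    return trees


def query_index(trees: dict, iv: GenomicInterval) -> list:
    tree = trees.get(iv.chrom)
    if tree is None:
        return []
    return [hit.data for hit in tree.overlap(iv.start, iv.end)]


def query_point(trees: dict, chrom: str, pos: int) -> list:
    tree = trees.get(chrom)
    if tree is None:
        return []
    return [hit.data for hit in tree.at(pos)]
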