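"""In-memory record types produced by the readers.

Every record carries 1-based inclusive coordinates; half-open on-disk
formats are converted exactly once, at the reader boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ..coords import GenomeRange

__all__ = [
    "ScoredInterval",
    "BedRecord",
    "GeneModel",
    "PairedInterval",
    "SnpRecord",
    "FormatError",
]


class FormatError(ValueError):
    """A malformed line in a genomic text file; names the line number."""

    def __init__(self, path: str, lineno: int | None, message: str):
        self.path = path
        self.lineno = lineno
        where = f"{path}:{lineno}" if lineno is not None else path
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True)
class ScoredInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    value: float

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"interval end < start: {self}")
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite interval value: {self}")


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    name: str = ""
    score: float | None = None
    strand: str = "."
    thick_start: int | None = None
    thick_end: int | None = None
    blocks: tuple[tuple[int, int], ...] | None = None  # (abs 1-based start, size)

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"BED end < start: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.blocks is not None:
            prev_end = None
            for bstart, bsize in self.blocks:
                bend = bstart + bsize - 1
                if bstart < self.start or bend > self.end:
                    raise ValueError(f"block {bstart}+{bsize} outside [{self.start},{self.end}]")
                if prev_end is not None and bstart <= prev_end:
                    raise ValueError("blocks unsorted or overlapping")
                prev_end = bend


@dataclass(frozen=True)
class GeneModel:
    gene_name: str
    chrom: str
    span: GenomeRange
    strand: str
    exons: tuple[GenomeRange, ...]
    transcript_id: str | None = None


@dataclass(frozen=True)
class PairedInterval:
    anchor1: GenomeRange
    anchor2: GenomeRange
    score: float | None = None

    def canonical(self) -> "PairedInterval":
        """Order anchors by (chrom, start)."""
        a, b = self.anchor1, self.anchor2
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            return PairedInterval(b, a, self.score)
        return self


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int  # 1-based
    pvalue: float

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.pvalue)
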