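"""Genome coordinates: ranges, chromosome sizes, binning and browser navigation.

All in-memory coordinates are 1-based inclusive (the genome-browser
convention users type into a location box).  On-disk half-open formats
(BED, bedGraph, BEDPE) are converted at the reader boundary, never here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "GenomeRange",
    "ChromSizes",
    "BinAxis",
    "parse_region",
    "range_to_bins",
    "zoom_range",
    "shift_range",
]


class RegionParseError(ValueError):
    """Raised for malformed region strings."""


_REGION_RE = re.compile(r"^(?P<chrom>\S+?)(?::(?P<start>[\d,]+)-(?P<end>[\d,]+))?$")


@dataclass(frozen=True, order=True)
class GenomeRange:
    """A 1-based, inclusive genomic interval.

    ``GenomeRange("chr1", 1000, 2000)`` covers bases 1000..2000, so its
    length is 1001 bp.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomeRange") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and self.end >= other.start
        )

    def contains(self, other: "GenomeRange") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersect(self, other: "GenomeRange") -> "GenomeRange | None":
        if not self.overlaps(other):
            return None
        return GenomeRange(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, mapping: Mapping[str, int] | None = None):
        super().__init__()
        if mapping:
            for chrom, size in mapping.items():
                self[chrom] = int(size)
                if self[chrom] <= 0:
                    raise ValueError(f"chromosome {chrom} has non-positive size")

    @classmethod
    def from_file(cls, path: str) -> "ChromSizes":
        """Read a two-column TSV (chrom, length)."""
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns")
                sizes[parts[0]] = int(parts[1])
        return cls(sizes)

    def full_range(self, chrom: str) -> GenomeRange:
        if chrom not in self:
            raise KeyError(f"chromosome {chrom!r} not in sizes table")
        return GenomeRange(chrom, 1, self[chrom])

    def clamp(self, grange: GenomeRange) -> GenomeRange:
        """Slide/clip ``grange`` so it lies within the chromosome.

        Length is preserved when the chromosome is long enough; otherwise
        the range becomes the full chromosome.
        """
        size = self.get(grange.chrom)
        if size is None:
            return grange
        length = len(grange)
        if length >= size:
            return GenomeRange(grange.chrom, 1, size)
        start, end = grange.start, grange.end
        if start < 1:
            start, end = 1, length
        if end > size:
            start, end = size - length + 1, size
        return GenomeRange(grange.chrom, start, end)


@dataclass(frozen=True)
class BinAxis:
    """Fixed-resolution binning of a genome range, anchored at range start.

    Bin ``i`` covers 1-based positions
    ``[start + i*resolution, min(start + (i+1)*resolution - 1, end)]``;
    the last bin may be partial.
    """

    range: GenomeRange
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def n_bins(self) -> int:
        return math.ceil(len(self.range) / self.resolution)

    def bin_range(self, i: int) -> GenomeRange:
        if not 0 <= i < self.n_bins:
            raise IndexError(f"bin {i} out of range (n_bins={self.n_bins})")
        start = self.range.start + i * self.resolution
        end = min(start + self.resolution - 1, self.range.end)
        return GenomeRange(self.range.chrom, start, end)

    def __iter__(self) -> Iterator[GenomeRange]:
        for i in range(self.n_bins):
            yield self.bin_range(i)

    def bin_of(self, pos: int) -> int:
        """Bin index containing the 1-based position ``pos``."""
        if not self.range.start <= pos <= self.range.end:
            raise ValueError(f"position {pos} outside {self.range}")
        return (pos - self.range.start) // self.resolution

    def edges(self) -> list[float]:
        """n_bins+1 bp edges for plotting (half-unit outside 1-based bins)."""
        out = [self.range.start - 0.5]
        for i in range(self.n_bins):
            out.append(self.bin_range(i).end + 0.5)
        return out


def parse_region(text: str, chromsizes: ChromSizes | None = None) -> GenomeRange:
    """Parse ``"chrom:start-end"`` (commas allowed) or bare ``"chrom"``.

    A bare chromosome name needs ``chromsizes`` to expand to the full
    chromosome.
    """
    if isinstance(text, GenomeRange):
        return text
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(f"cannot parse region string: {text!r}")
    chrom = m.group("chrom")
    if m.group("start") is None:
        if ":" in text:
            raise RegionParseError(f"cannot parse region string: {text!r}")
        if chromsizes is None:
            raise RegionParseError(
                f"bare chromosome {chrom!r} requires a chromosome-sizes table"
            )
        return chromsizes.full_range(chrom)
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if start < 1:
        raise ValueError(f"start must be >= 1 in {text!r}")
    if end < start:
        raise ValueError(f"end < start in {text!r}")
    return GenomeRange(chrom, start, end)


def range_to_bins(grange: GenomeRange, resolution: int) -> BinAxis:
    """Bin a range at ``resolution`` bp, keeping the last partial bin."""
    return BinAxis(grange, resolution)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def zoom_range(
    grange: GenomeRange, fold: float, chromsizes: ChromSizes | None = None
) -> GenomeRange:
    """Zoom about the range center: fold > 1 zooms in, fold < 1 out.

    The minimum window is 2 bp; the result is clamped to the chromosome
    when sizes are given.
    """
    if not fold > 0:
        raise ValueError(f"zoom fold must be positive, got {fold}")
    center = grange.center
    new_len = max(2, _round_half_away(len(grange) / fold))
    start = _round_half_away(center - (new_len - 1) / 2)
    start = max(1, start)
    out = GenomeRange(grange.chrom, start, start + new_len - 1)
    if chromsizes is not None and grange.chrom in chromsizes:
        out = chromsizes.clamp(out)
    return out


def shift_range(
    grange: GenomeRange, frac: float, chromsizes: ChromSizes | None = None
) -> GenomeRange:
    """Slide the window by ``frac`` of its span (negative = leftward).

    Length is preserved except flush against chromosome boundaries.
    """
    if not math.isfinite(frac):
        raise ValueError("shift fraction must be finite")
    offset = _round_half_away(frac * (grange.end - grange.start))
    start = grange.start + offset
    end = grange.end + offset
    if start < 1:
        end += 1 - start
        start = 1
    out = GenomeRange(grange.chrom, start, end)
    if chromsizes is not None and grange.chrom in chromsizes:
        out = chromsizes.clamp(out)
    return out
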