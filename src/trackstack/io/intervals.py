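"""Readers for bedGraph signal, BED annotations and SNP tables, plus
signal binning for histogram tracks."""

from __future__ import annotations

import logging
import math

import numpy as np

from ..coords import BinAxis, GenomeRange
from .query import query_records
from .records import BedRecord, FormatError, ScoredInterval, SnpRecord

log = logging.getLogger(__name__)

__all__ = ["read_scored_intervals", "read_bed", "read_snps", "bin_signal", "read_bigwig"]


def _parse_bedgraph(fields: list[str]):
    if len(fields) < 4:
        raise ValueError(f"bedGraph needs 4 columns, got {len(fields)}")
    chrom = fields[0]
    start0, end0 = int(fields[1]), int(fields[2])
    value = float(fields[3])
    if end0 <= start0:
        raise ValueError(f"empty interval [{start0},{end0})")
    # half-open 0-based -> 1-based inclusive
    rec = ScoredInterval(chrom, start0 + 1, end0, value)
    return chrom, rec.start, rec.end, rec


def read_scored_intervals(path: str, grange: GenomeRange) -> list[ScoredInterval]:
    """bedGraph records overlapping ``grange`` (any overlap), in file order.

    Records are returned un-clipped; display clipping is the caller's job.
    """
    return query_records(path, grange, _parse_bedgraph)


def _parse_bed(fields: list[str]):
    n = len(fields)
    if n < 3:
        raise ValueError(f"BED needs >= 3 columns, got {n}")
    chrom = fields[0]
    start = int(fields[1]) + 1
    end = int(fields[2])
    name = fields[3] if n >= 4 else ""
    score: float | None = None
    if n >= 5 and fields[4] not in (".", ""):
        score = float(fields[4])
    strand = fields[5] if n >= 6 and fields[5] in ("+", "-") else "."
    thick_start = thick_end = None
    if n >= 8:
        thick_start, thick_end = int(fields[6]) + 1, int(fields[7])
        if thick_end < thick_start:  # zero-width thick (no CDS)
            thick_start = thick_end = None
    blocks = None
    if n >= 12:
        count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != count or len(starts) != count:
            raise ValueError("blockCount disagrees with blockSizes/blockStarts")
        blocks = tuple((start + rel, size) for rel, size in zip(starts, sizes))
    rec = BedRecord(chrom, start, end, name, score, strand, thick_start, thick_end, blocks)
    return chrom, rec.start, rec.end, rec


def read_bed(path: str, grange: GenomeRange) -> list[BedRecord]:
    """BED3/6/9/12 records overlapping ``grange``, in file order."""
    return query_records(path, grange, _parse_bed)


_SNP_ALIASES = {
    "chrom": {"chrom", "chr", "chromosome"},
    "pos": {"pos", "position", "bp"},
    "pvalue": {"pvalue", "p-value", "p_value", "p", "pval"},
}


def _snp_header_map(path: str, colnames: dict[str, str]) -> dict[str, int]:
    """Resolve chrom/pos/pvalue column indices from the table's header line."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if line:
                break
        else:
            raise ValueError(f"{path}: empty SNP table")
    names = [f.lower().lstrip("#") for f in line.split("\t" if "\t" in line else None)]
    out: dict[str, int] = {}
    for role, wanted in colnames.items():
        aliases = _SNP_ALIASES.get(wanted, set()) | {wanted.lower()}
        for i, name in enumerate(names):
            if name in aliases:
                out[role] = i
                break
    missing = [colnames[r] for r in ("chrom", "pos", "pvalue") if r not in out]
    if missing:
        raise ValueError(f"{path}: SNP table header lacks columns: {missing}")
    return out


def read_snps(
    path: str,
    grange: GenomeRange,
    chrom_col: str = "chrom",
    pos_col: str = "pos",
    pvalue_col: str = "pvalue",
) -> list[SnpRecord]:
    """SNP TSV records in ``grange``; p outside (0,1] is dropped with a warning."""
    cols = _snp_header_map(
        path, {"chrom": chrom_col, "pos": pos_col, "pvalue": pvalue_col}
    )

    def parser(fields: list[str]):
        raw_pos = fields[cols["pos"]]
        if not raw_pos.lstrip("-").isdigit():
            return None  # header or junk line
        chrom = fields[cols["chrom"]]
        pos = int(raw_pos)
        p = float(fields[cols["pvalue"]])
        if not (0 < p <= 1):
            log.warning("rejecting SNP %s:%d with p-value %g outside (0, 1]", chrom, pos, p)
            return None
        rec = SnpRecord(chrom, pos, p)
        return chrom, pos, pos, rec

    return query_records(path, grange, parser)


def read_bigwig(path: str, grange: GenomeRange) -> list[ScoredInterval]:
    """Signal intervals from a bigWig file (delegated to pyBigWig)."""
    import pyBigWig

    out: list[ScoredInterval] = []
    with pyBigWig.open(str(path)) as bw:
        if grange.chrom not in bw.chroms():
            return out
        end = min(grange.end, bw.chroms()[grange.chrom])
        ivs = bw.intervals(grange.chrom, grange.start - 1, end) or []
        for s0, e0, v in ivs:
            if v is None or not math.isfinite(v):
                continue
            out.append(ScoredInterval(grange.chrom, s0 + 1, e0, float(v)))
    return out


def bin_signal(
    intervals: list[ScoredInterval], axis: BinAxis, stat: str = "mean"
) -> np.ndarray:
    """Aggregate interval values per display bin.

    ``mean`` is coverage-weighted over the bases each interval covers in
    the bin; ``sum`` is the coverage-weighted sum; ``max``/``min`` are
    over values of overlapping intervals.  Bins with no coverage are 0.
    """
    if stat not in ("mean", "max", "min", "sum"):
        raise ValueError(f"unknown stat {stat!r}")
    values = np.zeros(axis.n_bins, dtype=float)
    if not intervals:
        return values
    for i in range(axis.n_bins):
        brange = axis.bin_range(i)
        cov = 0
        acc = 0.0
        extremum: float | None = None
        for iv in intervals:
            if iv.chrom != brange.chrom:
                continue
            lo = max(iv.start, brange.start)
            hi = min(iv.end, brange.end)
            if lo > hi:
                continue
            nbase = hi - lo + 1
            cov += nbase
            acc += iv.value * nbase
            if extremum is None:
                extremum = iv.value
            elif stat == "max":
                extremum = max(extremum, iv.value)
            elif stat == "min":
                extremum = min(extremum, iv.value)
        if cov == 0:
            continue
        if stat == "mean":
            values[i] = acc / cov
        elif stat == "sum":
            values[i] = acc
        else:
            values[i] = extremum
    return values
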