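"""Reader for pairwise-interaction files: BEDPE and 4DN pairs.

The dialect is auto-detected (``#``-header sniffing plus column layout);
an explicit ``fmt`` argument overrides detection for ambiguous files.
"""

from __future__ import annotations

import gzip
import os

from ..coords import GenomeRange
from .query import iter_parsed_lines
from .records import FormatError, PairedInterval

__all__ = ["read_pairs", "detect_pairs_format"]


def _is_int(s: str) -> bool:
    return s.lstrip("-").isdigit()


def detect_pairs_format(path: str) -> str:
    """Return "bedpe" or "pairs"; raise FormatError when ambiguous."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first_data = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "pairs format" in line.lower():
                    return "pairs"
                continue
            first_data = line
            break
    if first_data is None:
        raise FormatError(str(path), None, "no data lines to detect dialect from")
    f = first_data.split("\t") if "\t" in first_data else first_data.split()
    # BEDPE: chrom1 start1 end1 chrom2 start2 end2 ...
    bedpe_like = (
        len(f) >= 6 and _is_int(f[1]) and _is_int(f[2]) and _is_int(f[4]) and _is_int(f[5])
        and not _is_int(f[3])
    )
    # pairs: readID chrom1 pos1 chrom2 pos2 ...
    pairs_like = (
        len(f) >= 5 and not _is_int(f[1]) and _is_int(f[2]) and not _is_int(f[3]) and _is_int(f[4])
    )
    if bedpe_like and not pairs_like:
        return "bedpe"
    if pairs_like and not bedpe_like:
        return "pairs"
    raise FormatError(
        str(path), None,
        "cannot auto-detect interaction dialect (BEDPE vs pairs); pass fmt= explicitly",
    )


def _parse_bedpe(fields: list[str]):
    if len(fields) < 6:
        raise ValueError(f"BEDPE needs >= 6 columns, got {len(fields)}")
    a1 = GenomeRange(fields[0], int(fields[1]) + 1, int(fields[2]))
    a2 = GenomeRange(fields[3], int(fields[4]) + 1, int(fields[5]))
    score = None
    if len(fields) >= 8 and fields[7] not in (".", ""):
        score = float(fields[7])
    rec = PairedInterval(a1, a2, score).canonical()
    return rec


def _parse_pairs(fields: list[str]):
    if len(fields) < 5:
        raise ValueError(f"pairs needs >= 5 columns, got {len(fields)}")
    a1 = GenomeRange(fields[1], int(fields[2]), int(fields[2]))
    a2 = GenomeRange(fields[3], int(fields[4]), int(fields[4]))
    return PairedInterval(a1, a2, None).canonical()


def read_pairs(
    path: str,
    range_h: GenomeRange,
    range_v: GenomeRange | None = None,
    rule: str = "either",
    fmt: str | None = None,
) -> list[PairedInterval]:
    """Interactions selected by anchor-overlap rule.

    * ``either`` — either anchor overlaps ``range_h`` (arcs track);
    * ``both``   — both anchors overlap ``range_h``;
    * ``cross``  — one anchor overlaps ``range_v`` and the other
      ``range_h``, in either order (joint 2D view).
    """
    if rule not in ("either", "both", "cross"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "cross" and range_v is None:
        raise ValueError("rule='cross' requires range_v")
    if fmt is None:
        fmt = detect_pairs_format(path)
    if fmt not in ("bedpe", "pairs"):
        raise FormatError(str(path), None, f"unknown interaction dialect {fmt!r}")
    parse = _parse_bedpe if fmt == "bedpe" else _parse_pairs

    def parser(fields: list[str]):
        rec = parse(fields)
        # index on anchor1; the rule filter below decides membership
        return rec.anchor1.chrom, rec.anchor1.start, rec.anchor1.end, rec

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out: list[PairedInterval] = []
    for _lineno, _c, _s, _e, rec in iter_parsed_lines(path, parser):
        if _keep(rec, range_h, range_v, rule):
            out.append(rec)
    return out


def _keep(
    rec: PairedInterval, range_h: GenomeRange, range_v: GenomeRange | None, rule: str
) -> bool:
    o1 = rec.anchor1.overlaps(range_h)
    o2 = rec.anchor2.overlaps(range_h)
    if rule == "either":
        return o1 or o2
    if rule == "both":
        return o1 and o2
    assert range_v is not None
    v1 = rec.anchor1.overlaps(range_v)
    v2 = rec.anchor2.overlaps(range_v)
    return (v1 and o2) or (v2 and o1)
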