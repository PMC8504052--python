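"""Region-query engine shared by the text-format readers.

Two access paths with bit-identical results:

* **indexed** — a bgzip-compressed file with a tabix ``.tbi`` (or ``.csi``)
  index next to it is queried through pysam without scanning the file;
* **linear** — plain (or gzipped, unindexed) text is scanned whole and
  filtered in memory.

Both paths feed the same line parser and the same 1-based any-overlap
filter, so which one answered a query is unobservable to callers.
"""

from __future__ import annotations

import gzip
import os
from typing import Callable, Iterator, TypeVar

from ..coords import GenomeRange
from .records import FormatError

T = TypeVar("T")

# parser(fields) -> (chrom, start_1based, end_1based, record) or None to skip
LineParser = Callable[[list[str]], "tuple[str, int, int, T] | None"]


def has_tabix_index(path: str) -> bool:
    return str(path).endswith(".gz") and (
        os.path.exists(str(path) + ".tbi") or os.path.exists(str(path) + ".csi")
    )


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_parsed_lines(
    path: str, parser: LineParser, comment: str = "#"
) -> Iterator[tuple[int, str, int, int, T]]:
    """Parse every data line of the file: yields (lineno, chrom, start, end, record)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(comment) or line.startswith("track") or line.startswith("browser"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                parsed = parser(fields)
            except FormatError:
                raise
            except Exception as exc:
                raise FormatError(str(path), lineno, f"malformed line: {exc}") from exc
            if parsed is None:
                continue
            chrom, start, end, record = parsed
            yield lineno, chrom, start, end, record


def query_records(
    path: str, grange: GenomeRange, parser: LineParser, comment: str = "#"
) -> list[T]:
    """Records whose 1-based span overlaps ``grange``, in file order.

    Uses the tabix index when present, otherwise a full linear scan;
    the two paths return identical lists.
    """
    if has_tabix_index(path):
        return _query_tabix(path, grange, parser, comment)
    out: list[T] = []
    for _lineno, chrom, start, end, rec in iter_parsed_lines(path, parser, comment):
        if chrom == grange.chrom and start <= grange.end and end >= grange.start:
            out.append(rec)
    return out


def _query_tabix(
    path: str, grange: GenomeRange, parser: LineParser, comment: str
) -> list[T]:
    import pysam

    out: list[T] = []
    with pysam.TabixFile(str(path)) as tbx:
        if grange.chrom not in tbx.contigs:
            return out
        # tabix takes 0-based half-open coordinates
        for line in tbx.fetch(grange.chrom, grange.start - 1, grange.end):
            if not line or line.startswith(comment):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                parsed = parser(fields)
            except FormatError:
                raise
            except Exception as exc:
                raise FormatError(str(path), None, f"malformed line: {exc}") from exc
            if parsed is None:
                continue
            chrom, start, end, rec = parsed
            if chrom == grange.chrom and start <= grange.end and end >= grange.start:
                out.append(rec)
    return out
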