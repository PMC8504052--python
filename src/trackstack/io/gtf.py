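"""GTF gene-model reader.

Exon features are grouped by ``gene_name`` (falling back to ``gene_id``)
into :class:`GeneModel` objects; a gene is returned when its *span*
(min..max over exons) overlaps the query, so genes partly outside the
view come back whole.  GTF coordinates are already 1-based inclusive.
"""

from __future__ import annotations

import logging
import re

from ..coords import GenomeRange
from .query import has_tabix_index, iter_parsed_lines
from .records import GeneModel

log = logging.getLogger(__name__)

__all__ = ["read_gtf_genes"]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def _parse_gtf_exon(fields: list[str]):
    if len(fields) < 9:
        raise ValueError(f"GTF needs 9 columns, got {len(fields)}")
    if fields[2] != "exon":
        return None
    chrom = fields[0]
    start, end = int(fields[3]), int(fields[4])
    strand = fields[6] if fields[6] in ("+", "-") else "."
    attrs = _parse_attributes(fields[8])
    name = attrs.get("gene_name") or attrs.get("gene_id")
    if not name:
        log.warning("skipping exon %s:%d-%d with neither gene_name nor gene_id", chrom, start, end)
        return None
    rec = (chrom, start, end, strand, name, attrs.get("transcript_id"))
    return chrom, start, end, rec


def _group_genes(exon_rows) -> list[GeneModel]:
    by_gene: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for chrom, start, end, strand, name, tx in exon_rows:
        key = (chrom, name)
        if key not in by_gene:
            by_gene[key] = []
            order.append(key)
        by_gene[key].append((start, end, strand, tx))
    genes = []
    for chrom, name in order:
        rows = by_gene[(chrom, name)]
        exons = _merge_exons(chrom, [(s, e) for s, e, _, _ in rows])
        strand = rows[0][2]
        tx = rows[0][3]
        span = GenomeRange(chrom, exons[0].start, exons[-1].end)
        genes.append(GeneModel(name, chrom, span, strand, tuple(exons), tx))
    return genes


def _merge_exons(chrom: str, spans: list[tuple[int, int]]) -> list[GenomeRange]:
    """Sort and merge overlapping/adjacent exon intervals (transcript union)."""
    spans = sorted(spans)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [GenomeRange(chrom, s, e) for s, e in merged]


def read_gtf_genes(path: str, grange: GenomeRange) -> list[GeneModel]:
    """Gene models whose span overlaps ``grange``, grouped from exon lines."""
    rows = []
    if has_tabix_index(path):
        import pysam

        with pysam.TabixFile(str(path)) as tbx:
            if grange.chrom not in tbx.contigs:
                return []
            # fetch the whole chromosome: a gene's span can overlap the
            # query even when none of its exons do (intron gap in view)
            for line in tbx.fetch(grange.chrom):
                fields = line.split("\t")
                parsed = _parse_gtf_exon(fields)
                if parsed is not None:
                    rows.append(parsed[3])
    else:
        for _lineno, chrom, _s, _e, rec in iter_parsed_lines(path, _parse_gtf_exon):
            if chrom == grange.chrom:
                rows.append(rec)
    return [g for g in _group_genes(rows) if g.span.overlaps(grange)]
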