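"""Built-in track types: the registry entries wiring readers to drawers.

The catalogue: XAxis, Spacer, BedGraph, BigWig, BED, GTF, Arcs, HiCMat,
Virtual4C, DiScore, InsuScore, HiCDiff, SNP.  Analytic tracks reference
a contact-matrix source and compute their score profile at fetch time,
so the drawn profile always matches the current view.
"""

from __future__ import annotations

from .analytics import diff_matrix, directionality_index, insulation_score, virtual_4c
from .coords import GenomeRange, parse_region
from .io import (
    read_bed,
    read_bigwig,
    read_contact_matrix,
    read_gtf_genes,
    read_pairs,
    read_scored_intervals,
    read_snps,
)
from .tracks import register_track_type

__all__ = ["BUILTIN_DEFAULTS"]


def _fetch_none(track, grange):
    return None


def _fetch_bedgraph(track, grange):
    return read_scored_intervals(track.source, grange)


def _fetch_bigwig(track, grange):
    return read_bigwig(track.source, grange)


def _fetch_bed(track, grange):
    return read_bed(track.source, grange)


def _fetch_gtf(track, grange):
    return read_gtf_genes(track.source, grange)


def _fetch_arcs(track, grange):
    fmt = track.props.get("fmt")
    return read_pairs(track.source, grange, rule=track.props.get("rule", "either") or "either",
                      fmt=fmt)


def _fetch_matrix(track, grange):
    balanced = bool(track.props.get("balanced", False))
    resolution = track.props.get("resolution")
    resolution = int(resolution) if resolution else None
    return read_contact_matrix(track.source, grange, grange,
                               resolution=resolution, balanced=balanced)


def _fetch_virtual4c(track, grange):
    matrix = _fetch_matrix(track, grange)
    anchor = track.props.get("anchor")
    if anchor is None:
        raise ValueError("Virtual4C track needs an 'anchor' prop (region string)")
    anchor = parse_region(anchor) if isinstance(anchor, str) else anchor
    return virtual_4c(matrix, anchor)


def _fetch_discore(track, grange):
    matrix = _fetch_matrix(track, grange)
    window = int(track.props.get("window", 10) or 10)
    return directionality_index(matrix, window)


def _fetch_insuscore(track, grange):
    matrix = _fetch_matrix(track, grange)
    window = int(track.props.get("window", 5) or 5)
    return insulation_score(matrix, window)


def _fetch_hicdiff(track, grange):
    sources = track.source
    if not isinstance(sources, (tuple, list)) or len(sources) != 2:
        raise ValueError("HiCDiff track needs two matrix sources [a, b]")
    balanced = bool(track.props.get("balanced", False))
    a = read_contact_matrix(sources[0], grange, grange, balanced=balanced)
    b = read_contact_matrix(sources[1], grange, grange, balanced=balanced)
    method = track.props.get("zscore", "per_distance") or "per_distance"
    return diff_matrix(a, b, method=method)


def _fetch_snp(track, grange):
    return read_snps(
        track.source, grange,
        chrom_col=track.props.get("chrom_col", "chrom") or "chrom",
        pos_col=track.props.get("pos_col", "pos") or "pos",
        pvalue_col=track.props.get("pvalue_col", "pvalue") or "pvalue",
    )


# Frozen per-type default style table (part of the documented interface).
BUILTIN_DEFAULTS: dict[str, dict] = {
    "XAxis": {"height": 0.5},
    "Spacer": {"height": 0.4},
    "BedGraph": {"height": 1.0, "color": "#4c72b0"},
    "BigWig": {"height": 1.0, "color": "#4c72b0"},
    "BED": {"height": 1.0, "color": "#2d6a4f", "style": "tile"},
    "GTF": {"height": 1.2, "color": "#1d3557", "style": "gene"},
    "Arcs": {"height": 1.2, "color": "#6a3d9a"},
    "HiCMat": {"height": 3.0, "style": "triangular", "color": "#b40426"},
    "Virtual4C": {"height": 1.0, "color": "#e76f51"},
    "DiScore": {"height": 1.0, "color": "#d62728"},
    "InsuScore": {"height": 1.0, "color": "#264653"},
    "HiCDiff": {"height": 3.0, "style": "square", "color": "#b40426"},
    "SNP": {"height": 1.2, "color": "#444444"},
}


def _register_builtins() -> None:
    from . import drawing as d

    register_track_type("XAxis", _fetch_none, d.draw_xaxis,
                        defaults=BUILTIN_DEFAULTS["XAxis"], needs_source=False)
    register_track_type("Spacer", _fetch_none, d.draw_spacer,
                        defaults=BUILTIN_DEFAULTS["Spacer"], needs_source=False)
    register_track_type("BedGraph", _fetch_bedgraph, d.draw_signal,
                        defaults=BUILTIN_DEFAULTS["BedGraph"])
    register_track_type("BigWig", _fetch_bigwig, d.draw_signal,
                        defaults=BUILTIN_DEFAULTS["BigWig"])
    register_track_type("BED", _fetch_bed, d.draw_bed, defaults=BUILTIN_DEFAULTS["BED"])
    register_track_type("GTF", _fetch_gtf, d.draw_genes, defaults=BUILTIN_DEFAULTS["GTF"])
    register_track_type("Arcs", _fetch_arcs, d.draw_arcs, defaults=BUILTIN_DEFAULTS["Arcs"])
    register_track_type("HiCMat", _fetch_matrix, d.draw_matrix,
                        defaults=BUILTIN_DEFAULTS["HiCMat"])
    register_track_type("Virtual4C", _fetch_virtual4c, d.draw_profile,
                        defaults=BUILTIN_DEFAULTS["Virtual4C"])
    register_track_type("DiScore", _fetch_discore, d.draw_profile,
                        defaults=BUILTIN_DEFAULTS["DiScore"])
    register_track_type("InsuScore", _fetch_insuscore, d.draw_profile,
                        defaults=BUILTIN_DEFAULTS["InsuScore"])
    register_track_type("HiCDiff", _fetch_hicdiff, d.draw_matrix,
                        defaults=BUILTIN_DEFAULTS["HiCDiff"])
    register_track_type("SNP", _fetch_snp, d.draw_snp, defaults=BUILTIN_DEFAULTS["SNP"])


_register_builtins()
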