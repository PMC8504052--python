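"""Per-track drawing primitives and layout geometry.

Every numerical decision (gene row packing, arc shape, matrix raster
transform) is computed here as plain data so tests can assert on
geometry without decoding rendered images.  Draw functions consume only
:class:`FetchResult` payloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coords import BinAxis, GenomeRange, range_to_bins
from .io.matrix import ContactMatrix
from .io.records import BedRecord, GeneModel, PairedInterval, ScoredInterval, SnpRecord

__all__ = [
    "layout_gene_rows",
    "arc_geometry",
    "matrix_panel_transform",
    "ArcSpec",
    "PanelTransform",
]


# ---------------------------------------------------------------- geometry

def layout_gene_rows(genes: list, min_gap: int = 0) -> dict:
    """Greedy first-fit packing of gene/interval spans into rows.

    Each gene goes to the lowest row whose last occupant ends at least
    ``min_gap`` bp before the gene starts.  ``genes`` must be sorted by
    span start; keys of the result are the genes themselves.
    """
    row_ends: list[int] = []
    placement: dict = {}
    for gene in genes:
        span = gene.span if isinstance(gene, GeneModel) else gene
        start = span.start if hasattr(span, "start") else span[0]
        end = span.end if hasattr(span, "end") else span[1]
        for row, last_end in enumerate(row_ends):
            if start - last_end >= max(min_gap, 1):
                row_ends[row] = end
                placement[gene] = row
                break
        else:
            row_ends.append(end)
            placement[gene] = len(row_ends) - 1
    return placement


@dataclass(frozen=True)
class ArcSpec:
    """Geometry of one interaction arc (before in-view height normalisation)."""

    x0: float  # anchor1 midpoint (bp)
    x1: float  # anchor2 midpoint (bp)
    apex_x: float
    span: float  # |x1 - x0|, proportional to un-normalised apex height
    score: float | None


def arc_geometry(pair: PairedInterval) -> ArcSpec:
    """Arc between anchor midpoints: apex centred, height proportional to span."""
    x0 = (pair.anchor1.start + pair.anchor1.end) / 2
    x1 = (pair.anchor2.start + pair.anchor2.end) / 2
    return ArcSpec(x0, x1, (x0 + x1) / 2, abs(x1 - x0), pair.score)


@dataclass(frozen=True)
class PanelTransform:
    """Drawable raster + colorbar description for a matrix panel."""

    mesh_x: np.ndarray  # (n+1, m+1) canvas x coordinates
    mesh_y: np.ndarray
    color_values: np.ndarray  # transformed + clamped values fed to the colormap
    vmin: float  # in transformed space
    vmax: float
    cmap: str
    scale: str  # "linear" | "log1p"
    clamp_data: tuple[float, float]  # colorbar labels, pre-transform units
    style: str  # "square" | "triangular"
    depth: float | None = None  # triangular: canvas height of the wedge


def _transform(values: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log1p":
        with np.errstate(invalid="ignore"):
            return np.log1p(np.clip(values, 0, None))
    if scale == "linear":
        return values
    raise ValueError(f"unknown scale {scale!r}")


def matrix_panel_transform(
    matrix: ContactMatrix,
    style: str = "triangular",
    scale: str = "log1p",
    cmap: str = "YlOrRd",
    clamp: tuple[float, float] | None = None,
    depth_ratio: float = 0.5,
) -> PanelTransform:
    """Raster coordinates and color mapping for a contact-matrix panel.

    ``triangular`` rotates the matrix 45 degrees and keeps the upper
    half, ``depth_ratio`` of the view span deep.  ``clamp`` bounds are
    in pre-transform (data) units; ``None`` picks the 2nd/98th
    percentile of finite values.  NaNs pass through for the renderer's
    bad-color.
    """
    if style not in ("square", "triangular"):
        raise ValueError(f"unknown matrix style {style!r}")
    values = np.asarray(matrix.values, dtype=float)
    finite = values[np.isfinite(values)]
    if clamp is None:
        if finite.size:
            lo, hi = np.percentile(finite, [2.0, 98.0])
            if lo == hi:
                lo, hi = float(finite.min()), float(finite.max() or 1.0)
            if lo == hi:
                hi = lo + 1.0
        else:
            lo, hi = 0.0, 1.0
        clamp = (float(lo), float(hi))
    t = _transform(values, scale)
    tlo, thi = _transform(np.array(clamp, dtype=float), scale)
    if tlo == thi:
        thi = tlo + 1.0
    color = np.clip(t, tlo, thi)

    row_edges = np.asarray(matrix.row_axis.edges())
    col_edges = np.asarray(matrix.col_axis.edges())
    if style == "square":
        mesh_x, mesh_y = np.meshgrid(col_edges, row_edges)
        return PanelTransform(
            mesh_x, mesh_y, color, float(tlo), float(thi), cmap, scale, clamp, style
        )
    # triangular: rotate 45 deg -> x = (u+v)/2, y = (v-u)/2 with u rows, v cols
    u, v = np.meshgrid(row_edges, col_edges, indexing="ij")
    mesh_x = (u + v) / 2
    mesh_y = (v - u) / 2
    # keep upper triangle only (y >= 0); mask cells below the diagonal
    n, m_ = color.shape
    ii, jj = np.meshgrid(np.arange(n), np.arange(m_), indexing="ij")
    color = np.where(jj >= ii, color, np.nan)
    span = matrix.col_axis.range.end - matrix.col_axis.range.start + 1
    depth = depth_ratio * span
    return PanelTransform(
        mesh_x, mesh_y, color, float(tlo), float(thi), cmap, scale, clamp, style, depth
    )


# ------------------------------------------------------------- draw helpers

def _set_pos_axis(ax, grange: GenomeRange, orientation: str):
    if orientation == "horizontal":
        ax.set_xlim(grange.start - 0.5, grange.end + 0.5)
    else:
        ax.set_ylim(grange.end + 0.5, grange.start - 0.5)  # position grows downward


def _pos_unit(span: float) -> tuple[float, str]:
    if span >= 2_000_000:
        return 1e6, "Mb"
    if span >= 2_000:
        return 1e3, "kb"
    return 1.0, "bp"


def draw_xaxis(ax, track, result, grange: GenomeRange, orientation="horizontal"):
    """Coordinate ruler: 5-10 nice round ticks with a kb/Mb unit suffix."""
    from matplotlib.ticker import MaxNLocator

    _set_pos_axis(ax, grange, orientation)
    scale, unit = _pos_unit(len(grange))
    locator = MaxNLocator(nbins=7, steps=[1, 2, 2.5, 5, 10], prune=None)
    ticks = [t for t in locator.tick_values(grange.start, grange.end)
             if grange.start - 0.5 <= t <= grange.end + 0.5]
    labels = [f"{t / scale:g}" for t in ticks]
    if labels:
        labels[-1] += f" {unit}"
    if orientation == "horizontal":
        ax.set_xticks(ticks, labels)
        ax.xaxis.set_ticks_position("top")
        ax.set_yticks([])
        ax.tick_params(labelsize=8)
        for side in ("left", "right", "bottom"):
            ax.spines[side].set_visible(False)
    else:
        ax.set_yticks(ticks, labels)
        ax.set_xticks([])
        ax.tick_params(labelsize=8)
        for side in ("top", "right", "bottom"):
            ax.spines[side].set_visible(False)
    ax.text(
        0.5 if orientation == "horizontal" else 0.05,
        0.05 if orientation == "horizontal" else 0.5,
        grange.chrom,
        transform=ax.transAxes,
        ha="center", va="bottom", fontsize=8,
        rotation=0 if orientation == "horizontal" else 90,
    )


def draw_spacer(ax, track, result, grange, orientation="horizontal"):
    """Blank vertical gap; consumes height, draws nothing."""
    ax.set_axis_off()
    _set_pos_axis(ax, grange, orientation)


def draw_signal(ax, track, result, grange, orientation="horizontal"):
    """Histogram of a scored-interval payload (bedGraph / bigWig)."""
    intervals: list[ScoredInterval] = result.payload or []
    n_bins = int(track.props.get("n_bins", 500) or 500)
    resolution = max(1, math.ceil(len(grange) / n_bins))
    axis = range_to_bins(grange, resolution)
    from .io.intervals import bin_signal

    stat = track.props.get("stat", "mean") or "mean"
    values = bin_signal(intervals, axis, stat=stat)
    edges = np.asarray(axis.edges())
    step_vals = np.append(values, values[-1]) if len(values) else np.array([0.0])
    color = track.props.color
    alpha = track.props.alpha
    lo = track.props.min_value if track.props.min_value is not None else min(0.0, values.min() if len(values) else 0.0)
    hi = track.props.max_value if track.props.max_value is not None else (values.max() if len(values) and values.max() > lo else lo + 1.0)
    if orientation == "horizontal":
        ax.fill_between(edges, step_vals, step="post", color=color, alpha=alpha, linewidth=0)
        _set_pos_axis(ax, grange, orientation)
        ax.set_ylim(lo, hi * 1.05 if hi > 0 else hi)
        ax.set_xticks([])
        ax.tick_params(labelsize=7)
    else:
        ax.fill_betweenx(edges, step_vals, step="post", color=color, alpha=alpha, linewidth=0)
        _set_pos_axis(ax, grange, orientation)
        ax.set_xlim(lo, hi * 1.05 if hi > 0 else hi)
        ax.set_yticks([])
        ax.tick_params(labelsize=7)


def draw_profile(ax, track, result, grange, orientation="horizontal"):
    """Analytic score profile (virtual 4C / DI / insulation)."""
    profile = result.payload
    centers = np.array([(b.start + b.end) / 2 for b in profile.axis])
    vals = np.asarray(profile.values, dtype=float)
    color = track.props.color
    if profile.kind == "di":
        pos = np.where(np.nan_to_num(vals) > 0, vals, 0)
        neg = np.where(np.nan_to_num(vals) < 0, vals, 0)
        width = profile.axis.resolution * 0.9
        if orientation == "horizontal":
            ax.bar(centers, pos, width=width, color="#d62728", linewidth=0)
            ax.bar(centers, neg, width=width, color="#1f77b4", linewidth=0)
        else:
            ax.barh(centers, pos, height=width, color="#d62728", linewidth=0)
            ax.barh(centers, neg, height=width, color="#1f77b4", linewidth=0)
    else:
        if orientation == "horizontal":
            ax.plot(centers, vals, color=color, linewidth=1.0)
        else:
            ax.plot(vals, centers, color=color, linewidth=1.0)
    _set_pos_axis(ax, grange, orientation)
    if orientation == "horizontal":
        ax.set_xticks([])
    else:
        ax.set_yticks([])
    ax.tick_params(labelsize=7)
    if track.props.min_value is not None or track.props.max_value is not None:
        lims = (track.props.min_value, track.props.max_value)
        if orientation == "horizontal":
            ax.set_ylim(*lims)
        else:
            ax.set_xlim(*lims)


def draw_bed(ax, track, result, grange, orientation="horizontal"):
    """BED tiles packed into rows; 12-column records show their blocks."""
    from matplotlib.patches import Rectangle

    records: list[BedRecord] = result.payload or []
    spans = sorted(records, key=lambda r: r.start)
    rows = layout_gene_rows(
        [GenomeRange(r.chrom, r.start, r.end) for r in spans],
        min_gap=int(track.props.get("min_gap", 1) or 1),
    )
    color = track.props.color
    n_rows = max(rows.values(), default=0) + 1
    for rec, span in zip(spans, rows):
        row = rows[span]
        y = n_rows - 1 - row
        if orientation == "horizontal":
            ax.add_patch(Rectangle((rec.start - 0.5, y + 0.2), rec.end - rec.start + 1,
                                   0.6, facecolor=color, alpha=track.props.alpha, linewidth=0))
            if rec.blocks:
                for bstart, bsize in rec.blocks:
                    ax.add_patch(Rectangle((bstart - 0.5, y + 0.05), bsize, 0.9,
                                           facecolor=color, linewidth=0))
        else:
            ax.add_patch(Rectangle((y + 0.2, rec.start - 0.5), 0.6, rec.end - rec.start + 1,
                                   facecolor=color, alpha=track.props.alpha, linewidth=0))
    _set_pos_axis(ax, grange, orientation)
    if orientation == "horizontal":
        ax.set_ylim(-0.1, max(n_rows, 1) + 0.1)
        ax.set_yticks([])
        ax.set_xticks([])
    else:
        ax.set_xlim(-0.1, max(n_rows, 1) + 0.1)
        ax.set_xticks([])
        ax.set_yticks([])


def draw_genes(ax, track, result, grange, orientation="horizontal"):
    """Gene models: exon boxes joined by an intron line, name above."""
    from matplotlib.patches import Rectangle

    genes: list[GeneModel] = sorted(result.payload or [], key=lambda g: g.span.start)
    rows = layout_gene_rows(genes, min_gap=int(track.props.get("min_gap", 1000) or 1000))
    color = track.props.color
    n_rows = max(rows.values(), default=0) + 1
    for gene, row in rows.items():
        y = n_rows - 1 - row
        if orientation == "horizontal":
            ax.plot([gene.span.start, gene.span.end], [y + 0.3, y + 0.3],
                    color=color, linewidth=0.8)
            for exon in gene.exons:
                ax.add_patch(Rectangle((exon.start - 0.5, y + 0.1),
                                       exon.end - exon.start + 1, 0.4,
                                       facecolor=color, linewidth=0))
            label = gene.gene_name + ({"+": " >", "-": " <"}.get(gene.strand, ""))
            ax.text((max(gene.span.start, grange.start) + min(gene.span.end, grange.end)) / 2,
                    y + 0.62, label, ha="center", va="bottom", fontsize=7)
        else:
            ax.plot([y + 0.3, y + 0.3], [gene.span.start, gene.span.end],
                    color=color, linewidth=0.8)
            for exon in gene.exons:
                ax.add_patch(Rectangle((y + 0.1, exon.start - 0.5), 0.4,
                                       exon.end - exon.start + 1,
                                       facecolor=color, linewidth=0))
    _set_pos_axis(ax, grange, orientation)
    if orientation == "horizontal":
        ax.set_ylim(-0.1, max(n_rows, 1) + 0.25)
        ax.set_yticks([])
        ax.set_xticks([])
    else:
        ax.set_xlim(-0.1, max(n_rows, 1) + 0.25)
        ax.set_xticks([])
        ax.set_yticks([])


def draw_arcs(ax, track, result, grange, orientation="horizontal"):
    """Interaction arcs: apex height proportional to span, width to score."""
    from matplotlib.patches import Arc as MplArc

    pairs: list[PairedInterval] = result.payload or []
    specs = [arc_geometry(p) for p in pairs]
    if not specs:
        _set_pos_axis(ax, grange, orientation)
        ax.set_yticks([]) if orientation == "horizontal" else ax.set_xticks([])
        return
    max_span = max(s.span for s in specs) or 1.0
    scores = [s.score for s in specs if s.score is not None]
    color = track.props.color
    for s in specs:
        h = s.span / max_span  # normalised apex height in [0, 1]
        if scores and s.score is not None:
            smin, smax = min(scores), max(scores)
            lw = 0.5 + 2.5 * ((s.score - smin) / (smax - smin) if smax > smin else 0.5)
        else:
            lw = 1.0
        if orientation == "horizontal":
            ax.add_patch(MplArc((s.apex_x, 0), s.span, 2 * h, theta1=0, theta2=180,
                                edgecolor=color, linewidth=lw, alpha=track.props.alpha))
        else:
            ax.add_patch(MplArc((0, s.apex_x), 2 * h, s.span, theta1=270, theta2=90,
                                edgecolor=color, linewidth=lw, alpha=track.props.alpha))
    _set_pos_axis(ax, grange, orientation)
    if orientation == "horizontal":
        ax.set_ylim(0, 1.05)
        ax.set_yticks([])
        ax.set_xticks([])
    else:
        ax.set_xlim(0, 1.05)
        ax.set_xticks([])
        ax.set_yticks([])


def _matrix_payload(payload):
    """Accept a bare ContactMatrix or a dict carrying {"matrix", "peaks"}."""
    if isinstance(payload, dict) and "matrix" in payload:
        return payload["matrix"], payload.get("peaks") or []
    return payload, []


def draw_matrix(ax, track, result, grange, orientation="horizontal"):
    """Contact-matrix heatmap (triangular by default) with inset colorbar."""
    import matplotlib as mpl

    matrix, peaks = _matrix_payload(result.payload)
    style = track.props.style or "triangular"
    scale = track.props.get("scale", "log1p") or "log1p"
    cmap_name = track.props.get("cmap") or ("bwr" if track.track_type == "HiCDiff" else "YlOrRd")
    clamp = None
    if track.props.min_value is not None and track.props.max_value is not None:
        clamp = (track.props.min_value, track.props.max_value)
    if track.track_type == "HiCDiff" and clamp is None:
        finite = matrix.values[np.isfinite(matrix.values)]
        amp = float(np.abs(finite).max()) if finite.size else 1.0
        clamp = (-amp, amp)
        scale = "linear"
    pt = matrix_panel_transform(matrix, style=style, scale=scale, cmap=cmap_name, clamp=clamp)
    cmap = mpl.colormaps[pt.cmap].copy()
    cmap.set_bad("#f0f0f0")
    masked = np.ma.masked_invalid(pt.color_values)
    mesh = ax.pcolormesh(pt.mesh_x, pt.mesh_y, masked, cmap=cmap, vmin=pt.vmin,
                         vmax=pt.vmax, shading="flat", rasterized=False)
    if style == "triangular":
        ax.set_xlim(grange.start - 0.5, grange.end + 0.5)
        ax.set_ylim(0, pt.depth)
    else:
        ax.set_xlim(matrix.col_axis.range.start - 0.5, matrix.col_axis.range.end + 0.5)
        ax.set_ylim(matrix.row_axis.range.end + 0.5, matrix.row_axis.range.start - 0.5)
    for (bi, bj) in _peak_bins(peaks):
        _mark_peak(ax, matrix, bi, bj, style)
    ax.set_xticks([])
    ax.set_yticks([])
    cax = ax.inset_axes([1.01, 0.1, 0.015, 0.8])
    cb = ax.figure.colorbar(mesh, cax=cax)
    cb.set_ticks([pt.vmin, pt.vmax])
    cb.set_ticklabels([f"{pt.clamp_data[0]:g}", f"{pt.clamp_data[1]:g}"])
    cb.ax.tick_params(labelsize=6)


def _peak_bins(peaks):
    for p in peaks:
        if isinstance(p, (tuple, list)) and len(p) >= 2:
            yield int(p[0]), int(p[1])


def _mark_peak(ax, matrix: ContactMatrix, bi: int, bj: int, style: str):
    from matplotlib.patches import Circle

    rr = matrix.row_axis.bin_range(min(bi, matrix.row_axis.n_bins - 1))
    cc = matrix.col_axis.bin_range(min(bj, matrix.col_axis.n_bins - 1))
    u = (rr.start + rr.end) / 2
    v = (cc.start + cc.end) / 2
    if style == "triangular":
        x, y = (u + v) / 2, abs(v - u) / 2
    else:
        x, y = v, u
    r = matrix.resolution * 0.7
    ax.add_patch(Circle((x, y), r, fill=False, edgecolor="#0000ff", linewidth=1.0))


def draw_snp(ax, track, result, grange, orientation="horizontal"):
    """Manhattan scatter of -log10 p along the view."""
    snps: list[SnpRecord] = result.payload or []
    xs = np.array([s.pos for s in snps], dtype=float)
    ys = np.array([s.neg_log10_p for s in snps], dtype=float)
    if orientation == "horizontal":
        ax.scatter(xs, ys, s=6, color=track.props.color, alpha=track.props.alpha, linewidths=0)
    else:
        ax.scatter(ys, xs, s=6, color=track.props.color, alpha=track.props.alpha, linewidths=0)
    _set_pos_axis(ax, grange, orientation)
    top = max(1.0, (ys.max() * 1.1) if len(ys) else 1.0)
    if track.props.max_value is not None:
        top = track.props.max_value
    if orientation == "horizontal":
        ax.set_ylim(0, top)
        ax.set_xticks([])
    else:
        ax.set_xlim(0, top)
        ax.set_yticks([])
    ax.tick_params(labelsize=7)


def draw_coverage(ax, coverage, grange, orientation="horizontal"):
    """Paint one Coverage overlay inside its target track's panel."""
    params = coverage.params
    if coverage.painter_type == "highlight_region":
        from .coords import parse_region

        region = params.get("region")
        region = parse_region(region) if isinstance(region, str) else region
        color = params.get("color", "#ffee00")
        alpha = float(params.get("alpha", 0.25))
        if orientation == "horizontal":
            ax.axvspan(region.start, region.end, color=color, alpha=alpha, linewidth=0)
        else:
            ax.axhspan(region.start, region.end, color=color, alpha=alpha, linewidth=0)
    elif coverage.painter_type == "vlines":
        color = params.get("color", "#555555")
        for pos in params.get("positions", []):
            if orientation == "horizontal":
                ax.axvline(float(pos), color=color, linewidth=0.8, alpha=0.8)
            else:
                ax.axhline(float(pos), color=color, linewidth=0.8, alpha=0.8)
    elif coverage.painter_type == "arcs_overlay":
        from .io.pairs import read_pairs

        pairs = read_pairs(params["path"], grange, rule="either")
        specs = [arc_geometry(p) for p in pairs]
        max_span = max((s.span for s in specs), default=1.0) or 1.0
        from matplotlib.patches import Arc as MplArc

        y0, y1 = ax.get_ylim()
        height = abs(y1 - y0)
        for s in specs:
            h = height * s.span / max_span
            ax.add_patch(MplArc((s.apex_x, min(y0, y1)), s.span, 2 * h, theta1=0,
                                theta2=180, edgecolor=params.get("color", "#2ca02c"),
                                linewidth=1.0, alpha=0.8))
    elif coverage.painter_type == "custom":
        coverage.painter(ax, grange, **params)
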