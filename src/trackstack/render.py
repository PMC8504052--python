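"""Deterministic rendering of frames and joint 2D views.

Figures are laid out as one panel per track, tiled vertically with
heights proportional to each track's ``height`` prop and a single
shared bp -> canvas transform.  Output formats: PNG, JPEG, PDF, SVG.
SVG output is canonicalised — creation date stripped, matplotlib's
element-id hash salt fixed — so identical inputs give byte-identical
files, which is what makes CLI/API parity and navigation statelessness
testable at the byte level.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .compose import Frame, frame_fetch_all
from .coords import GenomeRange, parse_region
from .drawing import draw_coverage
from .tracks import FetchResult, get_track_type

__all__ = [
    "LayoutPlan",
    "JointViewSpec",
    "plan_layout",
    "render_frame",
    "render_joint_view",
]

_FORMATS = ("png", "jpeg", "pdf", "svg")
_HASHSALT = "trackstack"  # fixed so SVG element ids are content-deterministic


@dataclass(frozen=True)
class LayoutPlan:
    """Vertical panel layout for a frame at a given range."""

    width: float  # inches
    panels: tuple[tuple[str, float], ...]  # (track_id, height in relative units)
    range: GenomeRange

    @property
    def total_height(self) -> float:
        return sum(h for _, h in self.panels)


def plan_layout(frame: Frame, grange: GenomeRange) -> LayoutPlan:
    panels = tuple((t.track_id, float(t.props.height)) for t in frame.tracks)
    return LayoutPlan(float(frame.frame_props.get("width", 10.0)), panels, grange)


def _normalize_format(out_path: str | None, fmt: str | None) -> str:
    if fmt is None:
        if out_path is None:
            raise ValueError("need an output path or an explicit format")
        fmt = os.path.splitext(str(out_path))[1].lstrip(".").lower()
    fmt = {"jpg": "jpeg"}.get(fmt, fmt)
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported output format {fmt!r} (use one of {_FORMATS})")
    return fmt


def _save(fig, out_path: str, fmt: str, dpi: int) -> None:
    with matplotlib.rc_context({"svg.hashsalt": _HASHSALT}):
        if fmt == "svg":
            fig.savefig(out_path, format=fmt, metadata={"Date": None})
        elif fmt == "pdf":
            fig.savefig(out_path, format=fmt, metadata={"CreationDate": None})
        else:
            fig.savefig(out_path, format=fmt, dpi=dpi)


def _draw_error_panel(ax, track_id: str, exc: Exception) -> None:
    ax.set_xticks([])
    ax.set_yticks([])
    for side in ax.spines.values():
        side.set_edgecolor("#cc0000")
    ax.text(0.5, 0.5, f"{track_id}: {exc}", transform=ax.transAxes,
            ha="center", va="center", fontsize=7, color="#cc0000", wrap=True)


def _draw_track_panel(ax, track, result, grange, orientation="horizontal") -> None:
    tt = get_track_type(track.track_type)
    if tt.draw is not None:
        tt.draw(ax, track, result, grange, orientation)
    for cov in track.coverages:
        draw_coverage(ax, cov, grange, orientation)
    title = track.props.title
    if title:
        ax.text(1.005, 0.5, title, transform=ax.transAxes, ha="left", va="center",
                fontsize=8, rotation=270 if orientation == "vertical" else 0)


def render_frame(
    frame: Frame,
    grange: GenomeRange | str,
    out_path: str | None,
    fmt: str | None = None,
    dpi: int = 150,
    strict: bool = False,
):
    """Render a frame at a range to PNG/JPEG/PDF/SVG.

    Fetch errors become red placeholder panels (the figure is still
    produced) unless ``strict`` is set, in which case the first error
    propagates and no file is written.
    """
    grange = parse_region(grange) if isinstance(grange, str) else grange
    fmt = _normalize_format(out_path, fmt)
    fig = build_frame_figure(frame, grange, strict=strict)
    try:
        if out_path is not None:
            _save(fig, str(out_path), fmt, dpi)
    finally:
        plt.close(fig)
    return out_path


def build_frame_figure(frame: Frame, grange: GenomeRange | str, strict: bool = False):
    """Build (but do not save) the frame's figure; one panel per track,
    panel heights proportional to each track's ``height`` prop."""
    grange = parse_region(grange) if isinstance(grange, str) else grange
    results = frame_fetch_all(frame, grange)
    if strict:
        for track_id, res in results.items():
            if isinstance(res, Exception):
                raise res
    plan = plan_layout(frame, grange)
    heights = [h for _, h in plan.panels] or [1.0]
    fig = plt.figure(figsize=(plan.width, sum(heights)))
    gs = fig.add_gridspec(
        nrows=max(len(frame.tracks), 1), ncols=1, height_ratios=heights,
        hspace=0.08, left=0.06, right=0.9, top=0.96, bottom=0.04,
    )
    try:
        for i, track in enumerate(frame.tracks):
            ax = fig.add_subplot(gs[i, 0])
            res = results[track.track_id]
            if isinstance(res, Exception):
                _draw_error_panel(ax, track.track_id, res)
            else:
                _draw_track_panel(ax, track, res, grange)
    except Exception:
        plt.close(fig)
        raise
    return fig


@dataclass
class JointViewSpec:
    """A center 2D contact heatmap plus up to four side frames.

    Top/bottom frames run along ``range_h`` (the heatmap's columns);
    left/right frames run along ``range_v`` (its rows), rotated 90
    degrees.  ``side_ratio`` sizes one side-frame track panel relative
    to the center square.
    """

    center: object  # a matrix-type Track
    range_h: GenomeRange
    range_v: GenomeRange
    side_frames: dict[str, Frame] = field(default_factory=dict)
    side_ratio: float = 0.22

    def __post_init__(self):
        self.range_h = parse_region(self.range_h) if isinstance(self.range_h, str) else self.range_h
        self.range_v = parse_region(self.range_v) if isinstance(self.range_v, str) else self.range_v
        bad = set(self.side_frames) - {"top", "bottom", "left", "right"}
        if bad:
            raise ValueError(f"unknown side-frame positions: {sorted(bad)}")


def fetch_joint_center(spec: JointViewSpec) -> FetchResult:
    """The center heatmap's data: the off-diagonal window (rows = range_v,
    cols = range_h) of the matrix track's source."""
    from .io.matrix import read_contact_matrix
    from .tracks import Track

    track = spec.center
    if not isinstance(track, Track):
        raise TypeError("JointViewSpec.center must be a matrix Track")
    balanced = bool(track.props.get("balanced", False))
    matrix = read_contact_matrix(track.source, spec.range_v, spec.range_h, balanced=balanced)
    return FetchResult(
        track_id=track.track_id,
        range=spec.range_h,
        payload=matrix,
        provenance={"source": track.source, "range_v": str(spec.range_v),
                    "range_h": str(spec.range_h)},
    )


def render_joint_view(
    spec: JointViewSpec,
    out_path: str | None,
    fmt: str | None = None,
    dpi: int = 150,
    strict: bool = False,
):
    """Render the joint 2D view: center heatmap with side frames.

    The on-diagonal case (``range_h == range_v``) yields a symmetric
    center matrix; off-diagonal windows magnify cis-remote or trans
    contacts alongside 1D genome features on each flank.
    """
    import matplotlib as mpl
    import numpy as np

    from .drawing import matrix_panel_transform

    fmt = _normalize_format(out_path, fmt)
    center_res = fetch_joint_center(spec)

    top = spec.side_frames.get("top")
    bottom = spec.side_frames.get("bottom")
    left = spec.side_frames.get("left")
    right = spec.side_frames.get("right")

    unit = spec.side_ratio
    row_heights = (
        [t.props.height * unit for t in top.tracks] if top else []
    ) + [1.0] + ([t.props.height * unit for t in bottom.tracks] if bottom else [])
    col_widths = (
        [t.props.height * unit for t in left.tracks] if left else []
    ) + [1.0] + ([t.props.height * unit for t in right.tracks] if right else [])

    size = 5.0  # center square, inches
    fig_w = size * sum(col_widths) + 1.0
    fig_h = size * sum(row_heights) + 0.5
    fig = plt.figure(figsize=(fig_w, fig_h))
    gs = fig.add_gridspec(
        nrows=len(row_heights), ncols=len(col_widths),
        height_ratios=row_heights, width_ratios=col_widths,
        hspace=0.05, wspace=0.05, left=0.07, right=0.93, top=0.95, bottom=0.05,
    )
    center_row = len(top.tracks) if top else 0
    center_col = len(left.tracks) if left else 0

    try:
        # center heatmap: rows = range_v (y, growing downward), cols = range_h
        ax = fig.add_subplot(gs[center_row, center_col])
        matrix = center_res.payload
        track = spec.center
        scale = track.props.get("scale", "log1p") or "log1p"
        cmap_name = track.props.get("cmap") or "YlOrRd"
        clamp = None
        if track.props.min_value is not None and track.props.max_value is not None:
            clamp = (track.props.min_value, track.props.max_value)
        pt = matrix_panel_transform(matrix, style="square", scale=scale,
                                    cmap=cmap_name, clamp=clamp)
        cmap = mpl.colormaps[pt.cmap].copy()
        cmap.set_bad("#f0f0f0")
        mesh = ax.pcolormesh(pt.mesh_x, pt.mesh_y, np.ma.masked_invalid(pt.color_values),
                             cmap=cmap, vmin=pt.vmin, vmax=pt.vmax, shading="flat")
        ax.set_xlim(matrix.col_axis.range.start - 0.5, matrix.col_axis.range.end + 0.5)
        ax.set_ylim(matrix.row_axis.range.end + 0.5, matrix.row_axis.range.start - 0.5)
        ax.set_xticks([])
        ax.set_yticks([])
        cax = ax.inset_axes([1.01, 0.1, 0.015, 0.8])
        cb = fig.colorbar(mesh, cax=cax)
        cb.set_ticks([pt.vmin, pt.vmax])
        cb.set_ticklabels([f"{pt.clamp_data[0]:g}", f"{pt.clamp_data[1]:g}"])
        cb.ax.tick_params(labelsize=6)

        def _paint_side(frame: Frame, grange: GenomeRange, horizontal: bool,
                        rows_or_cols: list[int]):
            results = frame_fetch_all(frame, grange)
            if strict:
                for res in results.values():
                    if isinstance(res, Exception):
                        raise res
            for k, tr in enumerate(frame.tracks):
                idx = rows_or_cols[k]
                sax = (fig.add_subplot(gs[idx, center_col]) if horizontal
                       else fig.add_subplot(gs[center_row, idx]))
                res = results[tr.track_id]
                if isinstance(res, Exception):
                    _draw_error_panel(sax, tr.track_id, res)
                else:
                    _draw_track_panel(sax, tr, res, grange,
                                      "horizontal" if horizontal else "vertical")

        if top:
            _paint_side(top, spec.range_h, True, list(range(0, len(top.tracks))))
        if bottom:
            first = center_row + 1
            _paint_side(bottom, spec.range_h, True,
                        list(range(first, first + len(bottom.tracks))))
        if left:
            _paint_side(left, spec.range_v, False, list(range(0, len(left.tracks))))
        if right:
            first = center_col + 1
            _paint_side(right, spec.range_v, False,
                        list(range(first, first + len(right.tracks))))

        if out_path is not None:
            _save(fig, str(out_path), fmt, dpi)
    finally:
        plt.close(fig)
    return out_path
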