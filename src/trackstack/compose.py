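"""The "+" composition algebra and the browser-state object.

Tracks, Frames, Features and Coverages combine with ``+`` (or the
:func:`compose` function, which the CLI's chained ``add`` verbs replay):

* Track + Track      -> Frame of the two, in order
* Frame + Track      -> Frame with the track appended
* Frame + Frame      -> concatenated Frame (one shared x-axis)
* Track/Frame + Feature -> style patch on that track / the frame's last
  track (scope "previous_track", the default) or on every track
  (scope "all_tracks")
* Track/Frame + Coverage -> overlay bound to that track / the last track

Composition never mutates its operands; every result is built from
copies, so a track reused in two frames styles independently.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Callable

from .coords import ChromSizes, GenomeRange, parse_region, shift_range, zoom_range
from .tracks import FetchResult, Track, fetch_track_data

__all__ = [
    "Frame",
    "Feature",
    "Coverage",
    "BrowserState",
    "compose",
    "frame_fetch_all",
    "browser_goto",
    "browser_zoom",
    "browser_shift",
    "CompositionError",
]


class CompositionError(TypeError):
    """Raised for undefined operand combinations."""


@dataclass
class Feature:
    """A style property patch applied through composition."""

    key: str
    value: Any
    scope: str = "previous_track"  # or "all_tracks"

    def __post_init__(self):
        if self.scope not in ("previous_track", "all_tracks"):
            raise ValueError(f"unknown Feature scope {self.scope!r}")

    def __radd__(self, other):
        return compose(other, self)


@dataclass
class Coverage:
    """An overlay painted inside its target track's panel."""

    painter_type: str  # {"highlight_region", "vlines", "arcs_overlay", "custom"}
    params: dict[str, Any] = field(default_factory=dict)
    painter: Callable | None = None  # for painter_type == "custom"

    _PAINTERS = ("highlight_region", "vlines", "arcs_overlay", "custom")

    def __post_init__(self):
        if self.painter_type not in self._PAINTERS:
            raise ValueError(f"unknown Coverage painter {self.painter_type!r}")
        if self.painter_type == "custom" and self.painter is None:
            raise ValueError("custom Coverage requires a painter callable")

    def __radd__(self, other):
        return compose(other, self)


class Frame:
    """An ordered vertical stack of tracks sharing one x-axis."""

    def __init__(
        self,
        tracks: list[Track] | None = None,
        current_range: GenomeRange | str | None = None,
        **frame_props: Any,
    ):
        tracks = [t.copy() for t in (tracks or [])]
        ids = [t.track_id for t in tracks]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate track ids in frame: {ids}")
        self.tracks = tracks
        self.current_range = (
            parse_region(current_range) if isinstance(current_range, str) else current_range
        )
        self.frame_props: dict[str, Any] = {"width": 10.0, "show_xaxis": True}
        self.frame_props.update(frame_props)

    @property
    def track_ids(self) -> list[str]:
        return [t.track_id for t in self.tracks]

    def copy(self) -> "Frame":
        new = Frame.__new__(Frame)
        new.tracks = [t.copy() for t in self.tracks]
        new.current_range = self.current_range
        new.frame_props = dict(self.frame_props)
        return new

    def goto(self, region: GenomeRange | str) -> "Frame":
        new = self.copy()
        new.current_range = parse_region(region) if isinstance(region, str) else region
        return new

    def __add__(self, other):
        return compose(self, other)

    def __len__(self) -> int:
        return len(self.tracks)

    def __repr__(self) -> str:
        return f"Frame({self.track_ids}, range={self.current_range})"

    def plot(self, region=None, out_path=None, **kwargs):
        from .render import render_frame

        grange = region if region is not None else self.current_range
        if grange is None:
            raise ValueError("no region set: pass one or goto() first")
        return render_frame(self, grange, out_path, **kwargs)

    def fetch_data(self, region=None) -> dict[str, FetchResult | Exception]:
        grange = region if region is not None else self.current_range
        if grange is None:
            raise ValueError("no region set")
        return frame_fetch_all(self, grange)


def compose(left: Any, right: Any) -> Any:
    """Combine two composable elements; returns a new value, never mutates."""
    if isinstance(left, Track) and isinstance(right, Track):
        return Frame([left, right])
    if isinstance(left, Frame) and isinstance(right, Track):
        new = left.copy()
        appended = right.copy()
        if appended.track_id in new.track_ids:
            raise ValueError(f"duplicate track id {appended.track_id!r} in frame")
        new.tracks.append(appended)
        return new
    if isinstance(left, Track) and isinstance(right, Frame):
        return compose(Frame([left]), right)
    if isinstance(left, Frame) and isinstance(right, Frame):
        new = left.copy()
        for t in right.tracks:
            new = compose(new, t)
        new.frame_props = {**right.frame_props, **left.frame_props}
        return new
    if isinstance(right, Feature):
        if isinstance(left, Track):
            new_t = left.copy()
            new_t.props.set(right.key, right.value)
            return new_t
        if isinstance(left, Frame):
            if not left.tracks:
                raise CompositionError("cannot apply a Feature to an empty Frame")
            new = left.copy()
            targets = new.tracks if right.scope == "all_tracks" else [new.tracks[-1]]
            for t in targets:
                t.props.set(right.key, right.value)
            return new
    if isinstance(right, Coverage):
        if isinstance(left, Track):
            new_t = left.copy()
            new_t.coverages.append(copy.deepcopy(right))
            return new_t
        if isinstance(left, Frame):
            if not left.tracks:
                raise CompositionError("cannot bind a Coverage to an empty Frame")
            new = left.copy()
            new.tracks[-1].coverages.append(copy.deepcopy(right))
            return new
    raise CompositionError(
        f"cannot compose {type(left).__name__} + {type(right).__name__}"
    )


def frame_fetch_all(
    frame: Frame, grange: GenomeRange | str
) -> dict[str, FetchResult | Exception]:
    """One FetchResult per track (errors collected per track, not raised)."""
    grange = parse_region(grange) if isinstance(grange, str) else grange
    out: dict[str, FetchResult | Exception] = {}
    for track in frame.tracks:
        try:
            out[track.track_id] = fetch_track_data(track, grange)
        except Exception as exc:  # collected, carries track_id in message
            out[track.track_id] = exc
    return out


@dataclass(frozen=True)
class BrowserState:
    """Immutable browser state: frame + current range + navigation history."""

    frame: Frame
    range: GenomeRange
    chromsizes: ChromSizes | None = None
    history: tuple[GenomeRange, ...] = ()

    def render(self, out_path=None, **kwargs):
        from .render import render_frame

        return render_frame(self.frame, self.range, out_path, **kwargs)


def browser_goto(state: BrowserState, region: GenomeRange | str) -> BrowserState:
    """Jump to a region; parse errors propagate and leave ``state`` usable."""
    grange = parse_region(region, state.chromsizes) if isinstance(region, str) else region
    return BrowserState(
        state.frame, grange, state.chromsizes, state.history + (state.range,)
    )


def browser_zoom(state: BrowserState, fold: float) -> BrowserState:
    return browser_goto(state, zoom_range(state.range, fold, state.chromsizes))


def browser_shift(state: BrowserState, frac: float) -> BrowserState:
    return browser_goto(state, shift_range(state.range, frac, state.chromsizes))
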