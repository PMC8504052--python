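"""The Track abstraction: typed, styled, data-bound plot elements.

A track type is a registered (fetch, draw) pair.  ``fetch`` turns a
genome range into the exact payload the renderer will draw — figures
and their data stay coupled — and custom types are built by inheriting
either function from a registered base, optionally adding only a
post-processing step on the fetched payload.
"""

from __future__ import annotations

import copy
import itertools
import os
import re
from dataclasses import dataclass, field
from typing import Any, Callable

from .coords import GenomeRange

__all__ = [
    "StyleProps",
    "Track",
    "FetchResult",
    "TrackType",
    "make_track",
    "fetch_track_data",
    "register_track_type",
    "registered_types",
    "type_defaults",
]

_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}([0-9a-fA-F]{2})?$")
_NAMED_COLORS = None  # lazy matplotlib lookup


def _valid_color(value: str) -> bool:
    global _NAMED_COLORS
    if _HEX_RE.match(value):
        return True
    if _NAMED_COLORS is None:
        from matplotlib.colors import get_named_colors_mapping

        _NAMED_COLORS = set(get_named_colors_mapping())
    return value in _NAMED_COLORS


class StyleProps:
    """Track style: known keys are validated at set time, unknown keys are
    preserved in ``extra`` and never dropped."""

    _KNOWN = ("color", "height", "alpha", "style", "min_value", "max_value", "title")

    def __init__(self, **kwargs: Any):
        self.color: str = "#4c72b0"
        self.height: float = 1.0
        self.alpha: float = 1.0
        self.style: str | None = None
        self.min_value: float | None = None
        self.max_value: float | None = None
        self.title: str = ""
        self.extra: dict[str, Any] = {}
        for key, value in kwargs.items():
            self.set(key, value)

    def set(self, key: str, value: Any) -> None:
        if key == "color":
            if not isinstance(value, str) or not _valid_color(value):
                raise ValueError(f"invalid value for prop 'color': {value!r}")
        elif key == "height":
            value = float(value)
            if not value > 0:
                raise ValueError(f"invalid value for prop 'height': {value!r} (must be > 0)")
        elif key == "alpha":
            value = float(value)
            if not 0 <= value <= 1:
                raise ValueError(f"invalid value for prop 'alpha': {value!r} (must be in [0,1])")
        elif key in ("min_value", "max_value") and value is not None:
            value = float(value)
        if key in self._KNOWN:
            setattr(self, key, value)
        else:
            self.extra[key] = value

    def get(self, key: str, default: Any = None) -> Any:
        if key in self._KNOWN:
            return getattr(self, key)
        return self.extra.get(key, default)

    def copy(self) -> "StyleProps":
        new = StyleProps.__new__(StyleProps)
        new.__dict__.update({k: v for k, v in self.__dict__.items() if k != "extra"})
        new.extra = dict(self.extra)
        return new

    def as_dict(self) -> dict[str, Any]:
        out = {k: getattr(self, k) for k in self._KNOWN}
        out.update(self.extra)
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, StyleProps) and self.as_dict() == other.as_dict()

    def __repr__(self) -> str:
        return f"StyleProps({self.as_dict()})"


@dataclass(frozen=True)
class FetchResult:
    """Payload bound to the range it was fetched for, with provenance."""

    track_id: str
    range: GenomeRange
    payload: Any
    provenance: dict[str, Any] = field(default_factory=dict)


@dataclass
class TrackType:
    """A registered track type: how to fetch and how to draw."""

    tag: str
    fetch: Callable[["Track", GenomeRange], Any] | None
    draw: Callable | None
    defaults: dict[str, Any] = field(default_factory=dict)
    needs_source: bool = True
    post_fetch: Callable[[Any, "Track", GenomeRange], Any] | None = None
    base: str | None = None


_REGISTRY: dict[str, TrackType] = {}
_ids = itertools.count(1)


def register_track_type(
    tag: str,
    fetch_fn: Callable | None = None,
    draw_fn: Callable | None = None,
    base: str | None = None,
    post_fetch: Callable | None = None,
    defaults: dict[str, Any] | None = None,
    needs_source: bool | None = None,
) -> TrackType:
    """Register a track type, optionally inheriting from ``base``.

    With a base, ``fetch_fn``/``draw_fn`` may be omitted and are
    inherited; a type that only post-processes the base's payload needs
    to supply nothing but ``post_fetch``.
    """
    if tag in _REGISTRY:
        raise ValueError(f"track type {tag!r} is already registered")
    parent = None
    if base is not None:
        if base not in _REGISTRY:
            raise ValueError(f"base track type {base!r} is not registered")
        parent = _REGISTRY[base]
    fetch = fetch_fn if fetch_fn is not None else (parent.fetch if parent else None)
    draw = draw_fn if draw_fn is not None else (parent.draw if parent else None)
    if fetch is None and draw is None:
        raise ValueError(f"track type {tag!r}: neither fetch nor draw resolvable")
    merged_defaults = dict(parent.defaults) if parent else {}
    merged_defaults.update(defaults or {})
    if needs_source is None:
        needs_source = parent.needs_source if parent else True
    tt = TrackType(
        tag=tag,
        fetch=fetch,
        draw=draw,
        defaults=merged_defaults,
        needs_source=needs_source,
        post_fetch=post_fetch if post_fetch is not None else (parent.post_fetch if parent else None),
        base=base,
    )
    _REGISTRY[tag] = tt
    return tt


def unregister_track_type(tag: str) -> None:
    _REGISTRY.pop(tag, None)


def registered_types() -> list[str]:
    return sorted(_REGISTRY)


def get_track_type(tag: str) -> TrackType:
    if tag not in _REGISTRY:
        raise ValueError(f"track type {tag!r} is not registered")
    return _REGISTRY[tag]


def type_defaults(tag: str) -> dict[str, Any]:
    """The documented per-type default style table."""
    return dict(get_track_type(tag).defaults)


class Track:
    """A single data-bound plot element."""

    def __init__(
        self,
        track_type: str,
        source: Any = None,
        track_id: str | None = None,
        props: StyleProps | None = None,
    ):
        tt = get_track_type(track_type)
        self.track_type = track_type
        self.source = source
        self.track_id = track_id or f"{track_type.lower()}_{next(_ids)}"
        self.props = props.copy() if props is not None else StyleProps()
        if props is None:
            for key, value in tt.defaults.items():
                self.props.set(key, value)
        self.coverages: list = []

    def copy(self) -> "Track":
        new = Track.__new__(Track)
        new.track_type = self.track_type
        new.source = copy.copy(self.source)
        new.track_id = self.track_id
        new.props = self.props.copy()
        new.coverages = [copy.deepcopy(c) for c in self.coverages]
        return new

    def __add__(self, other):
        from .compose import compose

        return compose(self, other)

    def __repr__(self) -> str:
        return f"Track({self.track_type}, id={self.track_id!r}, source={self.source!r})"


def _source_paths(source: Any) -> list[str]:
    if source is None:
        return []
    if isinstance(source, (tuple, list)):
        out: list[str] = []
        for s in source:
            out.extend(_source_paths(s))
        return out
    s = str(source)
    if "::" in s:
        return [p for p in s.split("::") if p]
    return [s]


def make_track(
    track_type: str, source: Any = None, track_id: str | None = None, **props: Any
) -> Track:
    """Create a validated track with per-type default styling applied."""
    tt = get_track_type(track_type)
    if tt.needs_source:
        if source is None:
            raise ValueError(f"track type {track_type!r} requires a data source")
        for path in _source_paths(source):
            if not os.path.exists(path):
                raise FileNotFoundError(f"track source not readable: {path}")
    track = Track(track_type, source, track_id)
    for key, value in props.items():
        track.props.set(key, value)
    return track


# fetch cache: (track_id, range, params-hash) -> (mtimes, FetchResult)
_FETCH_CACHE: dict[tuple, tuple[tuple, FetchResult]] = {}


def _params_key(track: Track) -> tuple:
    items = []
    for k, v in sorted(track.props.as_dict().items()):
        try:
            hash(v)
        except TypeError:
            v = repr(v)
        items.append((k, v))
    return (repr(track.source), tuple(items))


def _mtimes(track: Track) -> tuple:
    return tuple(
        os.path.getmtime(p) if os.path.exists(p) else None for p in _source_paths(track.source)
    )


def fetch_track_data(track: Track, grange: GenomeRange | str) -> FetchResult:
    """Fetch the exact data the next render of ``grange`` will draw.

    Results are cached per (track, range, params) and invalidated when
    any source file's modification time changes.
    """
    from .coords import parse_region

    grange = parse_region(grange) if isinstance(grange, str) else grange
    tt = get_track_type(track.track_type)
    key = (track.track_id, str(grange), _params_key(track))
    mtimes = _mtimes(track)
    cached = _FETCH_CACHE.get(key)
    if cached is not None and cached[0] == mtimes:
        return cached[1]
    if tt.fetch is None:
        payload = None
    else:
        try:
            payload = tt.fetch(track, grange)
        except Exception as exc:
            exc.args = (f"[track {track.track_id}] {exc}",)
            raise
    if tt.post_fetch is not None:
        payload = tt.post_fetch(payload, track, grange)
    result = FetchResult(
        track_id=track.track_id,
        range=grange,
        payload=payload,
        provenance={"source": track.source, "track_type": track.track_type,
                    "params": dict(track.props.extra)},
    )
    _FETCH_CACHE[key] = (mtimes, result)
    return result


def clear_fetch_cache() -> None:
    _FETCH_CACHE.clear()
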