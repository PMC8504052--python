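"""Contact-matrix container and the HiC-Pro sparse-format reader.

A HiC-Pro matrix is a pair of files: a bins BED (chrom, start, end,
bin_id, [weight]) and a triplet file ("bin1 bin2 count", 1-based bin
ids, upper triangle).  The two paths are given as a ``(bins, matrix)``
tuple or a single ``"bins.bed::mat.matrix"`` string.  ``.cool`` files
are handed to the optional ``cooler`` package when it is installed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

from ..coords import BinAxis, GenomeRange
from .records import FormatError

__all__ = ["ContactMatrix", "read_contact_matrix", "MatrixSource"]


@dataclass(frozen=True)
class ContactMatrix:
    """Dense binned contact matrix over one (square) or two bin axes."""

    row_axis: BinAxis
    col_axis: BinAxis
    values: np.ndarray  # n_rows x n_cols, float, NaN = missing
    resolution: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.row_axis.n_bins, self.col_axis.n_bins):
            raise ValueError(
                f"matrix shape {v.shape} disagrees with axes "
                f"({self.row_axis.n_bins}, {self.col_axis.n_bins})"
            )

    @property
    def is_square(self) -> bool:
        return self.row_axis == self.col_axis

    @property
    def axis(self) -> BinAxis:
        if not self.is_square:
            raise ValueError("off-diagonal matrix has two distinct axes")
        return self.row_axis

    def with_values(self, values: np.ndarray) -> "ContactMatrix":
        return ContactMatrix(self.row_axis, self.col_axis, values, self.resolution)


@dataclass(frozen=True)
class MatrixSource:
    """Paths of a HiC-Pro sparse matrix (bins BED + triplets)."""

    bins_path: str
    matrix_path: str

    @classmethod
    def parse(cls, source) -> "MatrixSource | str":
        if isinstance(source, MatrixSource):
            return source
        if isinstance(source, (tuple, list)) and len(source) == 2:
            return cls(str(source[0]), str(source[1]))
        s = str(source)
        if "::" in s:
            bins, mat = s.split("::", 1)
            return cls(bins, mat)
        return s  # single path: cooler or error later


def _load_bins(bins_path: str):
    """Per-chrom bin table: chrom -> {grid_index: (bin_id, start0, end0, weight)}."""
    if not os.path.exists(bins_path):
        raise FileNotFoundError(bins_path)
    by_chrom: dict[str, dict[int, tuple[int, int, int, float]]] = {}
    widths: list[int] = []
    has_weights = False
    with open(bins_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 4:
                raise FormatError(bins_path, lineno, "bins BED needs 4 columns (chrom start end id)")
            chrom, start0, end0, bin_id = f[0], int(f[1]), int(f[2]), int(f[3])
            weight = float("nan")
            if len(f) >= 5:
                has_weights = True
                weight = float(f[4]) if f[4] not in (".", "") else float("nan")
            widths.append(end0 - start0)
            by_chrom.setdefault(chrom, {})
            by_chrom[chrom][start0] = (bin_id, start0, end0, weight)
    if not widths:
        raise FormatError(bins_path, None, "empty bins table")
    resolution = max(widths)  # last bin per chromosome may be partial
    return by_chrom, resolution, has_weights


def _grid_bins(by_chrom, resolution: int, grange: GenomeRange):
    """File bins covering ``grange``, snapped outward to the bin grid.

    Returns (snapped BinAxis, ordered bin descriptors).
    """
    chrom_bins = by_chrom.get(grange.chrom)
    if not chrom_bins:
        raise ValueError(f"chromosome {grange.chrom!r} absent from bins table")
    b0 = (grange.start - 1) // resolution
    b1 = (grange.end - 1) // resolution
    selected = []
    for k in range(b0, b1 + 1):
        start0 = k * resolution
        if start0 in chrom_bins:
            selected.append(chrom_bins[start0])
    if not selected:
        raise ValueError(f"no matrix bins overlap {grange}")
    snapped = GenomeRange(grange.chrom, selected[0][1] + 1, selected[-1][2])
    return BinAxis(snapped, resolution), selected


def read_contact_matrix(
    source,
    range_row: GenomeRange,
    range_col: GenomeRange | None = None,
    resolution: int | None = None,
    balanced: bool = False,
) -> ContactMatrix:
    """Dense contact matrix for a (possibly off-diagonal) window.

    Absent triplets are 0; the on-diagonal (``range_row == range_col``)
    result is exactly symmetric.  ``balanced=True`` multiplies entry
    (i, j) by ``weight_i * weight_j`` from the bins table's weight
    column and errors when the file has none.
    """
    from ..coords import parse_region

    if isinstance(range_row, str):
        range_row = parse_region(range_row)
    if isinstance(range_col, str):
        range_col = parse_region(range_col)
    src = MatrixSource.parse(source)
    if isinstance(src, str):
        if src.endswith((".cool", ".mcool")):
            return _read_cooler(src, range_row, range_col, resolution, balanced)
        raise ValueError(
            f"cannot interpret matrix source {src!r}: expected 'bins.bed::matrix' "
            "or a (bins, matrix) pair, or a .cool file"
        )
    if range_col is None:
        range_col = range_row

    by_chrom, file_res, has_weights = _load_bins(src.bins_path)
    if resolution is not None and resolution != file_res:
        raise ValueError(
            f"requested resolution {resolution} != file bin size {file_res} "
            f"({src.bins_path})"
        )
    if balanced and not has_weights:
        raise ValueError(f"balanced=True but {src.bins_path} has no weight column")

    row_axis, row_bins = _grid_bins(by_chrom, file_res, range_row)
    col_axis, col_bins = _grid_bins(by_chrom, file_res, range_col)
    row_index = {b[0]: i for i, b in enumerate(row_bins)}
    col_index = {b[0]: j for j, b in enumerate(col_bins)}
    all_ids = {b[0] for bins in by_chrom.values() for b in bins.values()}

    values = np.zeros((len(row_bins), len(col_bins)), dtype=float)
    if not os.path.exists(src.matrix_path):
        raise FileNotFoundError(src.matrix_path)
    with open(src.matrix_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 3:
                raise FormatError(src.matrix_path, lineno, "triplet needs 3 columns")
            try:
                b1, b2, count = int(f[0]), int(f[1]), float(f[2])
            except ValueError as exc:
                raise FormatError(src.matrix_path, lineno, str(exc)) from exc
            if b1 not in all_ids or b2 not in all_ids:
                raise FormatError(
                    src.matrix_path, lineno, f"bin id {b1 if b1 not in all_ids else b2} not in bins table"
                )
            # a triplet contributes wherever either orientation lands in the window
            if b1 in row_index and b2 in col_index:
                values[row_index[b1], col_index[b2]] = count
            if b2 in row_index and b1 in col_index:
                values[row_index[b2], col_index[b1]] = count

    if balanced:
        wr = np.array([b[3] for b in row_bins])
        wc = np.array([b[3] for b in col_bins])
        values = values * wr[:, None] * wc[None, :]

    return ContactMatrix(row_axis, col_axis, values, file_res)


def _read_cooler(path, range_row, range_col, resolution, balanced):
    try:
        import cooler  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "reading .cool/.mcool requires the optional 'cooler' package; "
            "HiC-Pro sparse text (bins.bed::matrix) needs no extra dependency"
        ) from exc
    if range_col is None:
        range_col = range_row
    uri = path
    clr = cooler.Cooler(uri)
    if resolution is not None and clr.binsize != resolution:
        raise ValueError(f"requested resolution {resolution} != cooler bin size {clr.binsize}")
    res = clr.binsize
    fetch = clr.matrix(balance=balanced, sparse=False)
    sub = fetch.fetch(str(range_row), str(range_col))
    b0r = (range_row.start - 1) // res
    b1r = (range_row.end - 1) // res
    b0c = (range_col.start - 1) // res
    b1c = (range_col.end - 1) // res
    row_axis = BinAxis(GenomeRange(range_row.chrom, b0r * res + 1, (b1r + 1) * res), res)
    col_axis = BinAxis(GenomeRange(range_col.chrom, b0c * res + 1, (b1c + 1) * res), res)
    return ContactMatrix(row_axis, col_axis, np.asarray(sub, dtype=float), res)
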