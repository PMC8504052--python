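"""Analytic transforms of Hi-C contact matrices.

Implements the score tracks that accompany a contact-matrix view:

* **virtual 4C** — a one-anchor contact profile mimicking a 4C experiment;
* **directionality index** (DI) — the signed chi-square-like statistic of
  Dixon et al. contrasting a bin's upstream and downstream contact sums,
  whose sign flips at TAD boundaries;
* **insulation score** — the Crane et al. diamond score: log2 of the mean
  contact in a w x w window sliding along the diagonal, relative to its
  profile-wide mean, with minima marking boundaries;
* **per-distance z-scoring** and the **differential matrix** built from it,
  which removes the distance-decay so local structure differences stand out.

Scores keep NaN where they are undefined (matrix edges, missing data);
display layers decide what to do with them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coords import BinAxis, GenomeRange
from .io.matrix import ContactMatrix

__all__ = [
    "ScoreProfile",
    "virtual_4c",
    "directionality_index",
    "insulation_score",
    "zscore_by_distance",
    "diff_matrix",
]


@dataclass(frozen=True)
class ScoreProfile:
    """A per-bin score vector aligned to a matrix bin axis."""

    axis: BinAxis
    values: np.ndarray
    kind: str  # {"virtual4c", "di", "insulation"}

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.axis.n_bins,):
            raise ValueError(f"profile length {v.shape} != n_bins {self.axis.n_bins}")

    def to_bedgraph(self, path: str) -> None:
        """Write the profile as bedGraph (0-based half-open), skipping NaNs."""
        with open(path, "w") as fh:
            for i, v in enumerate(self.values):
                if not np.isfinite(v):
                    continue
                br = self.axis.bin_range(i)
                fh.write(f"{br.chrom}\t{br.start - 1}\t{br.end}\t{v:g}\n")


def _require_square(matrix: ContactMatrix) -> np.ndarray:
    if not matrix.is_square:
        raise ValueError("analytic scores need a square (on-diagonal) matrix")
    return np.asarray(matrix.values, dtype=float)


def virtual_4c(matrix: ContactMatrix, anchor: GenomeRange) -> ScoreProfile:
    """Mean contact of the anchor bin(s) with every bin of the view.

    A single-bin anchor is an exact row extraction; a wider anchor takes
    the column-wise mean over its rows (NaN-propagating, so an all-NaN
    anchor yields an all-NaN profile).
    """
    m = _require_square(matrix)
    axis = matrix.axis
    if anchor.chrom != axis.range.chrom or not anchor.overlaps(axis.range):
        raise ValueError(f"anchor {anchor} outside matrix range {axis.range}")
    lo = axis.bin_of(max(anchor.start, axis.range.start))
    hi = axis.bin_of(min(anchor.end, axis.range.end))
    rows = m[lo : hi + 1, :]
    values = rows.mean(axis=0)
    return ScoreProfile(axis, values, "virtual4c")


def directionality_index(matrix: ContactMatrix, window: int) -> ScoreProfile:
    """Dixon-style directionality index with a ``window``-bin arm.

    For bin i, with A the contact sum over the ``window`` upstream bins
    and B over the downstream bins, E = (A+B)/2:

        DI_i = sign(B - A) * ((A-E)^2/E + (B-E)^2/E)

    DI_i = 0 when A = B or E = 0; bins within ``window`` of either edge
    are NaN.
    """
    m = _require_square(matrix)
    n = matrix.axis.n_bins
    if window < 1:
        raise ValueError("window must be >= 1")
    if window >= n:
        raise ValueError(f"window {window} must be < n_bins {n}")
    values = np.full(n, np.nan)
    for i in range(window, n - window):
        up = m[i, i - window : i]
        down = m[i, i + 1 : i + window + 1]
        a = np.nansum(up) if np.isfinite(up).any() else np.nan
        b = np.nansum(down) if np.isfinite(down).any() else np.nan
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        e = (a + b) / 2
        if a == b or e == 0:
            values[i] = 0.0
        else:
            chi = (a - e) ** 2 / e + (b - e) ** 2 / e
            values[i] = np.sign(b - a) * chi
    return ScoreProfile(matrix.axis, values, "di")


def insulation_score(matrix: ContactMatrix, window: int) -> ScoreProfile:
    """Crane-style diamond insulation score, log2-normalised.

    raw_i is the NaN-aware mean of the ``window`` x ``window`` block of
    contacts crossing bin boundary i (rows i-w..i-1, columns i..i+w-1);
    the reported score is log2(raw_i / mean of all valid raw values).
    Bins lacking a full diamond are NaN.
    """
    m = _require_square(matrix)
    n = matrix.axis.n_bins
    w = window
    if w < 1:
        raise ValueError("window must be >= 1")
    if w > (n - 1) / 2:
        raise ValueError(f"window {w} too large for {n} bins (need w <= (n-1)/2)")
    raw = np.full(n, np.nan)
    for i in range(w, n - w + 1):
        block = m[i - w : i, i : i + w]
        if np.isfinite(block).any():
            raw[i] = np.nanmean(block)
    valid = raw[np.isfinite(raw)]
    if valid.size == 0:
        raise ValueError("insulation undefined: no valid diamond windows")
    mean = valid.mean()
    if mean <= 0:
        raise ValueError("insulation undefined: non-positive mean diamond contact")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(raw / mean)
    return ScoreProfile(matrix.axis, values, "insulation")


def zscore_by_distance(matrix: ContactMatrix) -> ContactMatrix:
    """Z-score every diagonal of a square matrix independently.

    Entries at diagonal offset d become (x - mu_d) / sigma_d with the
    population mean/SD over finite entries of that diagonal; a diagonal
    with sigma = 0 or fewer than 2 finite entries is set to 0.  The
    output is re-symmetrised.  This removes the distance-decay trend so
    differences between matrices highlight local structure.
    """
    m = _require_square(matrix).copy()
    n = m.shape[0]
    out = np.full_like(m, np.nan)
    for d in range(n):
        idx = np.arange(n - d)
        diag = m[idx, idx + d]
        finite = np.isfinite(diag)
        if finite.sum() < 2:
            z = np.where(np.isfinite(diag), 0.0, np.nan)
        else:
            mu = diag[finite].mean()
            sigma = diag[finite].std()  # population SD
            if sigma == 0:
                z = np.where(finite, 0.0, np.nan)
            else:
                z = (diag - mu) / sigma
        out[idx, idx + d] = z
        out[idx + d, idx] = z
    return matrix.with_values(out)


def zscore_global(matrix: ContactMatrix) -> ContactMatrix:
    """Z-score the whole matrix against its global finite mean/SD."""
    m = _require_square(matrix)
    finite = np.isfinite(m)
    if finite.sum() < 2:
        return matrix.with_values(np.where(finite, 0.0, np.nan))
    mu = m[finite].mean()
    sigma = m[finite].std()
    if sigma == 0:
        return matrix.with_values(np.where(finite, 0.0, np.nan))
    return matrix.with_values((m - mu) / sigma)


def diff_matrix(
    a: ContactMatrix, b: ContactMatrix, method: str = "per_distance"
) -> ContactMatrix:
    """Difference of z-score-normalised matrices: z(a) - z(b).

    ``method`` selects per-diagonal ("per_distance", default) or global
    z-scoring.  Axes and resolution must match exactly; NaN wherever
    either input is NaN.
    """
    if a.row_axis != b.row_axis or a.col_axis != b.col_axis or a.resolution != b.resolution:
        raise ValueError(
            f"matrix axes differ: {a.row_axis.range}@{a.resolution} vs "
            f"{b.row_axis.range}@{b.resolution}"
        )
    zfn = {"per_distance": zscore_by_distance, "global": zscore_global}.get(method)
    if zfn is None:
        raise ValueError(f"unknown z-score method {method!r}")
    za = zfn(a).values
    zb = zfn(b).values
    return a.with_values(za - zb)
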