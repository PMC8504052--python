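# Methods

This note documents the models, conventions and design choices behind
trackstack: what each computation assumes, which knobs matter, what the
synthetic datasets emulate, and where the edges are.

## Coordinate model

All in-memory coordinates are **1-based inclusive**, the convention of
genome-browser location boxes (`chr1:1,000-2,000` covers 1001 bases).
Half-open 0-based formats (BED, bedGraph, BEDPE) are converted exactly
once, at the reader boundary; GTF is already 1-based inclusive and
passes through. Whether displayed coordinates should be 0- or 1-based
is a convention choice, not something derivable from any one file
format; we fixed 1-based inclusive and convert everything at read time.

Region queries use **any-overlap** semantics (a record overlapping the
view by a single base is returned, un-clipped), matching how browsers
show genes running off-screen. Binning anchors at the *range start*
rather than absolute position 0 and keeps the last partial bin, so a
track plots exactly the requested window. The one exception is
contact-matrix queries: the file's bins are anchored at position 0 on
disk, so matrix windows snap *outward* to the file's bin grid and the
returned axis reflects the snapped range — callers can see exactly
which window they got.

Navigation arithmetic (`zoom_range`, `shift_range`) rounds half away
from zero, enforces a 2 bp minimum window, and slides flush against
chromosome boundaries when a sizes table is given (length preserved
except at the edge). These rules are conventions frozen by tests, not
facts about any data.

## Readers and the indexed-access contract

Every text reader answers a region query by one of two paths with
**bit-identical** results: a pysam/tabix indexed fetch when a `.tbi`
(or `.csi`) sits next to a bgzipped file, or a whole-file linear scan
otherwise. Both paths share one line parser and one overlap filter, so
which path answered is unobservable; the test suite runs them against
each other. GTF is the one reader that always groups a whole
chromosome before filtering: a gene whose exons flank the view must
still be returned (its span overlaps via an intron), which a
range-restricted fetch would miss.

Interaction files (BEDPE / 4DN pairs) are auto-detected from header
sniffing plus column layout, with an explicit `fmt=` override for
ambiguous files, and are always linearly scanned — no standard
single-coordinate index covers two anchors. Anchors are canonically
ordered by (chrom, start). Three overlap rules serve three consumers:
`either` (arcs tracks), `both`, and `cross` (joint 2D views).

The HiC-Pro sparse pair (bins BED + upper-triangle `bin1 bin2 count`
triplets, 1-based ids) is the reference matrix format. Absent triplets
are 0; on-diagonal windows are mirror-filled to exact symmetry. The
official bins BED has no weight column; we accept an optional fifth
numeric column as balancing weights so `balanced=True` can multiply
entry (i,j) by `w_i·w_j`, and error when no weights exist — this
package reads pre-computed weights and deliberately implements no
balancing algorithm. `.cool` support delegates to the optional
`cooler` package when installed.

`bin_signal` aggregates intervals into display bins with a
coverage-weighted mean (or max/min/sum) over covered bases;
zero-coverage bins are **0**, not NaN, so signal histograms have no
visual gaps. NaN is reserved for matrix data and analytic scores.

## Hi-C analytics

The score tracks adopt the canonical published definitions, since
"directionality index" and "insulation score" name families rather
than formulas:

* **Directionality index** — the Dixon-style signed chi-square-like
  statistic (see README for the formula). Forced to 0 when the
  upstream and downstream sums tie or their mean is 0; NaN within one
  window of either matrix edge. DI scales linearly with a uniform
  scaling of the matrix (asserted, not assumed, in tests).
* **Insulation score** — the Crane-style w×w diamond mean sliding
  along the diagonal, reported as log2 relative to the mean over valid
  positions, which makes it invariant to uniform scaling. Window `w`
  must satisfy `w ≤ (n−1)/2`; default 5 bins for the built-in track.
* **Virtual 4C** — row extraction for a single-bin anchor, NaN-
  propagating column-wise mean over anchor rows otherwise. An all-NaN
  anchor yields an all-NaN profile by design.
* **z-scored differential matrices** — each diagonal offset is
  standardised independently (population SD; a diagonal with σ=0 or
  fewer than 2 finite entries becomes 0) before subtracting, because
  per-distance normalisation removes the dominant distance-decay trend
  and lets condition differences show local structure. A global-z
  variant is selectable (`method="global"`); per-distance is the
  default and the documented behaviour.

Analytic scores never silently convert NaN to 0 — display layers
decide what undefined bins look like.

## Tracks, composition, rendering

A track type is a registered **(fetch, draw)** pair; `fetch` maps a
range to the exact payload `draw` consumes, with results cached per
(track, range, params) and invalidated by source-file mtime. Custom
types inherit either function from a base type and may supply *only* a
`post_fetch` payload transformer — the designed path for "matrix plus
called peaks"-style tracks, where the novel computation is the only
code the author writes.

Composition (`+`) is **immutable**: every result is built from copies,
so a track reused in two frames styles independently and CLI replay
equals API construction exactly. A `Feature` patches the previous
track by default (scope `all_tracks` for frame-wide properties);
whether a style patch should bind backwards or forwards is a pure
convention — backwards matches how one reads a chain aloud, and is
frozen in tests. `Frame + Frame` concatenates rather than nests: one
shared x-axis per figure.

Rendering is deterministic by construction: matplotlib's SVG id hash
salt is fixed and date metadata stripped, so identical inputs give
byte-identical SVG across processes — the property that makes CLI/API
parity and navigation statelessness testable at the byte level rather
than by pixel comparison. Panel heights are proportional to each
track's `height` prop; the shared bp→canvas transform is identical
across panels. Numerical conventions: triangular matrix panels rotate
the upper triangle 45° with depth = half the view span (configurable);
auto color clamping uses the 2nd/98th percentiles of finite values;
colorbar labels show pre-transform units even under `log1p`; x-axis
rulers pick 5–10 round ticks with a kb/Mb suffix. Fetch errors render
as red placeholder panels unless `strict`, in which case no file is
written.

The joint 2D view reads the center window as rows = vertical range,
columns = horizontal range; top/bottom side frames run along the
horizontal range and left/right along the vertical one, rotated 90°.
The side-frame/center size ratio defaults to 0.22 per track-height
unit (a config knob, `side_ratio`). In the CLI, `joint <source>
range_v=<region>` declares the center; at `plot` the composed frame
serves as the top and left side frames with the `goto` range
horizontal.

## The chained CLI

Verbs separated by a literal `-` token, props as `key=value` — this
grammar is part of the package's frozen interface, round-trips through
`CliProgram.format()`, and replays through the same `compose` calls
the API uses. A `--config` file holds one verb per line with identical
syntax, so a figure's recipe is a five-line text file. `fetch` prints
the current view's payload as TSV with per-type headers.

## Synthetic data

`generate_dataset` writes a two-chromosome genome (chr1 500 kb, chr2
300 kb, 10 kb matrix resolution by default) covering every supported
format, with a JSON manifest of the planted truth; same seed, same
bytes. What it emulates, and what it does not:

* **Signal** — 1 kb piecewise-constant tiles with uniform(0,10)
  values recorded per-interval in the manifest. Real coverage has
  autocorrelation and peaks; this generator trades realism for exact
  per-interval ground truth, which is what reader oracles need.
* **Contact matrices** — `round(C·exp(−|i−j|/ℓ))` with C=100, ℓ=5
  bins, +50 inside each planted TAD block, +200 at the planted loop
  cell, optional seeded Poisson resampling (off by default so analytic
  scores are checked exactly against construction). The constants are
  sized so DI/insulation/z-diff signals sit far from degeneracy; the
  loop lives off the TAD blocks so its z-diff argmax is unambiguous.
  Real Hi-C has compartments, chromosome-scale decay mixtures and
  mapping artifacts — none are modelled, so passing tests demonstrate
  algorithmic correctness, not robustness to real-data noise.
* **Genes** — 2–5 exons drawn on a 40 kb span grid; BED12 blocks are
  derived from the same models the GTF writes, exercising both
  readers on one truth.

## Problem sizes and limits

The full test suite runs ~210 tests in well under a minute;
`scripts/acceptance.py` finishes in a few seconds using 200 region
queries per format (1400 total), 50 random 40×40 matrices, exhaustive
composition permutations to n=4 and five parity figures — sizes at
which every check is exact rather than sampled thin.

Known limitations: no BAM track, no `.hic` binary format, no matrix
balancing computation, no liftover or multi-range split views, no
plugin discovery for third-party track packages, and bigWig reading
(delegated to pyBigWig) sits outside the bit-exact oracle suite since
its binary layout has no linear-scan oracle. The ipython-widget style
interactive panel is out of scope; the navigation *operations* it
would drive (goto/zoom/slide as pure functions on browser state) are
fully implemented and tested.
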