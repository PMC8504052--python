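"""Seeded synthetic datasets covering every supported input format.

The generator writes a small two-chromosome genome's worth of files —
bedGraph signal, BED3/6/12 annotations, GTF gene models, BEDPE loops,
4DN pairs, a SNP table and a HiC-Pro sparse contact matrix — together
with a JSON manifest of the planted ground truth (TAD boundaries, loop
bins, per-interval signal values).  Regeneration with the same seed is
byte-identical, so rendered figures built on these files are too.

The contact matrix is an exponential distance-decay Toeplitz base with
an in-TAD contact bonus inside each planted block and point enrichments
at planted loops; Poisson resampling is optional and off by default so
analytic scores can be checked exactly against construction.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .coords import BinAxis, ChromSizes, GenomeRange
from .io.matrix import ContactMatrix

__all__ = ["FixtureManifest", "generate_dataset", "planted_matrix"]

# Construction constants: decay amplitude, in-TAD bonus and decay length
# are sized so DI / insulation / z-diff signals sit well away from zero.
DEFAULT_C = 100.0
DEFAULT_TAD_BONUS = 50.0
DEFAULT_DECAY_LENGTH = 5.0
DEFAULT_LOOP_STRENGTH = 200.0


@dataclass
class FixtureManifest:
    """Machine-readable ground truth for one generated dataset."""

    seed: int
    chromsizes: dict[str, int]
    resolution: int
    planted_tad_boundaries: list[int]
    planted_loops: list[tuple[int, int, float]]
    signal_functions: dict[str, str]
    files: dict[str, str]
    ground_truth: dict[str, list] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "FixtureManifest":
        with open(path) as fh:
            data = json.load(fh)
        data["planted_loops"] = [tuple(x) for x in data["planted_loops"]]
        return cls(**data)


def planted_matrix(
    n_bins: int,
    boundaries: list[int] | None = None,
    loops: list[tuple[int, int, float]] | None = None,
    decay_length: float = DEFAULT_DECAY_LENGTH,
    noise: str = "off",
    seed: int | None = None,
    base_count: float = DEFAULT_C,
    tad_bonus: float = DEFAULT_TAD_BONUS,
    chrom: str = "chr1",
    resolution: int = 10_000,
) -> ContactMatrix:
    """Symmetric contact matrix with planted TAD blocks and loops.

    ``base[i,j] = round(C * exp(-|i-j| / decay_length))`` plus
    ``tad_bonus`` when i and j fall in the same planted block (blocks
    are the segments between ``boundaries``) plus the loop strength at
    each planted (i, j) and its mirror.  ``noise="poisson"`` resamples
    every entry (seeded) while keeping symmetry.
    """
    boundaries = sorted(boundaries or [])
    loops = loops or []
    for b in boundaries:
        if not 0 < b < n_bins:
            raise ValueError(f"boundary {b} not strictly inside (0, {n_bins})")
    idx = np.arange(n_bins)
    base = np.round(base_count * np.exp(-np.abs(idx[:, None] - idx[None, :]) / decay_length))
    values = base.copy()
    if boundaries:  # no boundaries -> no planted blocks -> pure decay
        edges = [0] + boundaries + [n_bins]
        block_of = np.empty(n_bins, dtype=int)
        for k in range(len(edges) - 1):
            block_of[edges[k] : edges[k + 1]] = k
        same_block = block_of[:, None] == block_of[None, :]
        values = values + np.where(same_block, tad_bonus, 0.0)
    for (i, j, strength) in loops:
        if not (0 <= i < n_bins and 0 <= j < n_bins):
            raise ValueError(f"loop bin ({i},{j}) outside matrix")
        values[i, j] += strength
        if i != j:
            values[j, i] += strength
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        upper = np.triu(rng.poisson(values).astype(float))
        values = upper + np.triu(upper, 1).T
    elif noise != "off":
        raise ValueError(f"unknown noise mode {noise!r}")
    axis = BinAxis(GenomeRange(chrom, 1, n_bins * resolution), resolution)
    return ContactMatrix(axis, axis, values, resolution)


def _write_bedgraph(path: str, rows: list[tuple[str, int, int, float]]) -> None:
    with open(path, "w") as fh:
        for chrom, s0, e0, v in rows:
            fh.write(f"{chrom}\t{s0}\t{e0}\t{v:.3f}\n")


def _write_matrix_files(
    bins_path: str, matrix_path: str, matrices: dict[str, ContactMatrix],
    chromsizes: dict[str, int], resolution: int, weights: dict[str, np.ndarray] | None = None,
) -> None:
    """HiC-Pro pair: one bins table over all chromosomes, upper-triangle triplets."""
    bin_id = 0
    id_of: dict[tuple[str, int], int] = {}
    with open(bins_path, "w") as fh:
        for chrom in sorted(chromsizes):
            size = chromsizes[chrom]
            n = math.ceil(size / resolution)
            for k in range(n):
                bin_id += 1
                id_of[(chrom, k)] = bin_id
                s0 = k * resolution
                e0 = min((k + 1) * resolution, size)
                if weights is not None:
                    w = weights[chrom][k]
                    fh.write(f"{chrom}\t{s0}\t{e0}\t{bin_id}\t{w:.4f}\n")
                else:
                    fh.write(f"{chrom}\t{s0}\t{e0}\t{bin_id}\n")
    with open(matrix_path, "w") as fh:
        for chrom in sorted(matrices):
            m = matrices[chrom].values
            n = m.shape[0]
            for i in range(n):
                for j in range(i, n):
                    if m[i, j] != 0:
                        fh.write(f"{id_of[(chrom, i)]}\t{id_of[(chrom, j)]}\t{m[i, j]:g}\n")


def generate_dataset(
    outdir: str,
    seed: int = 0,
    chromsizes: dict[str, int] | None = None,
    resolution: int = 10_000,
) -> FixtureManifest:
    """Write the full fixture dataset into ``outdir`` and return its manifest."""
    os.makedirs(outdir, exist_ok=True)
    chromsizes = dict(chromsizes or {"chr1": 500_000, "chr2": 300_000})
    rng = np.random.default_rng(seed)
    p = lambda name: os.path.join(outdir, name)
    files: dict[str, str] = {}
    truth: dict[str, list] = {}

    # chromosome sizes table
    files["chromsizes"] = p("chrom.sizes")
    with open(files["chromsizes"], "w") as fh:
        for chrom in sorted(chromsizes):
            fh.write(f"{chrom}\t{chromsizes[chrom]}\n")

    # bedGraph: 1 kb piecewise-constant tiles with recorded values
    tile = 1000
    bg_rows: list[tuple[str, int, int, float]] = []
    for chrom in sorted(chromsizes):
        size = chromsizes[chrom]
        for s0 in range(0, size, tile):
            e0 = min(s0 + tile, size)
            bg_rows.append((chrom, s0, e0, float(np.round(rng.uniform(0, 10), 3))))
    files["bedgraph"] = p("signal.bedgraph")
    _write_bedgraph(files["bedgraph"], bg_rows)
    truth["bedgraph"] = [[c, s, e, v] for c, s, e, v in bg_rows]

    # BED6 annotations: random sorted intervals
    bed_rows = []
    for chrom in sorted(chromsizes):
        size = chromsizes[chrom]
        starts = np.sort(rng.integers(0, size - 5000, size=40))
        for k, s0 in enumerate(starts):
            e0 = int(s0) + int(rng.integers(500, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            bed_rows.append((chrom, int(s0), min(e0, size), f"feat_{chrom}_{k}",
                             int(rng.integers(0, 1000)), strand))
    files["bed"] = p("annotations.bed")
    with open(files["bed"], "w") as fh:
        for row in bed_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    truth["bed"] = [list(r) for r in bed_rows]

    # gene models: GTF + the same genes as BED12
    genes = []
    for chrom in sorted(chromsizes):
        size = chromsizes[chrom]
        n_genes = 8 if chrom == "chr1" else 5
        gstarts = np.sort(rng.integers(5000, size - 60_000, size=n_genes))
        for g, gs in enumerate(gstarts):
            n_exons = int(rng.integers(2, 6))
            exon_starts = np.sort(rng.choice(np.arange(0, 40_000, 800), size=n_exons,
                                             replace=False))
            exons = []
            for es in exon_starts:
                elen = int(rng.integers(200, 700))
                exons.append((int(gs) + int(es) + 1, int(gs) + int(es) + elen))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append({"name": f"GENE{chrom[3:]}_{g}", "chrom": chrom,
                          "strand": strand, "exons": exons})
    files["gtf"] = p("genes.gtf")
    with open(files["gtf"], "w") as fh:
        for gene in genes:
            for t, (es, ee) in enumerate(gene["exons"]):
                attrs = (f'gene_id "{gene["name"]}"; gene_name "{gene["name"]}"; '
                         f'transcript_id "{gene["name"]}.1";')
                fh.write(f"{gene['chrom']}\tfixture\texon\t{es}\t{ee}\t.\t"
                         f"{gene['strand']}\t.\t{attrs}\n")
    files["bed12"] = p("genes12.bed")
    with open(files["bed12"], "w") as fh:
        for gene in genes:
            span_s0 = gene["exons"][0][0] - 1
            span_e0 = gene["exons"][-1][1]
            sizes = ",".join(str(ee - es + 1) for es, ee in gene["exons"])
            rels = ",".join(str(es - 1 - span_s0) for es, _ in gene["exons"])
            fh.write(f"{gene['chrom']}\t{span_s0}\t{span_e0}\t{gene['name']}\t0\t"
                     f"{gene['strand']}\t{span_s0}\t{span_e0}\t0\t"
                     f"{len(gene['exons'])}\t{sizes}\t{rels}\n")
    truth["genes"] = genes

    # planted contact matrices (chr1 carries the structure)
    n_bins = math.ceil(chromsizes["chr1"] / resolution)
    boundary = n_bins // 2
    loop = (n_bins // 5, 4 * n_bins // 5, DEFAULT_LOOP_STRENGTH)
    mat_a = planted_matrix(n_bins, [boundary], [loop], resolution=resolution)
    mat_b = planted_matrix(n_bins, [boundary], [], resolution=resolution)
    files["matrix_bins"] = p("hicpro_abs.bed")
    files["matrix"] = p("hicpro.matrix")
    _write_matrix_files(files["matrix_bins"], files["matrix"], {"chr1": mat_a},
                        chromsizes, resolution)
    files["matrix_noloop_bins"] = p("hicpro_noloop_abs.bed")
    files["matrix_noloop"] = p("hicpro_noloop.matrix")
    _write_matrix_files(files["matrix_noloop_bins"], files["matrix_noloop"],
                        {"chr1": mat_b}, chromsizes, resolution)
    # weighted variant for the balanced-read contract
    wts = {c: np.round(rng.uniform(0.5, 1.5, size=math.ceil(chromsizes[c] / resolution)), 4)
           for c in sorted(chromsizes)}
    files["matrix_weighted_bins"] = p("hicpro_weighted_abs.bed")
    files["matrix_weighted"] = p("hicpro_weighted.matrix")
    _write_matrix_files(files["matrix_weighted_bins"], files["matrix_weighted"],
                        {"chr1": mat_a}, chromsizes, resolution, weights=wts)
    truth["weights"] = {c: wts[c].tolist() for c in wts}

    # BEDPE: planted loops as anchor spans + a few extra pairs
    bedpe_rows = []
    for (i, j, strength) in [loop]:
        a_s0, a_e0 = i * resolution, (i + 1) * resolution
        b_s0, b_e0 = j * resolution, (j + 1) * resolution
        bedpe_rows.append(("chr1", a_s0, a_e0, "chr1", b_s0, b_e0,
                           "loop_0", f"{strength:g}", "+", "-"))
    extra_anchors = np.sort(rng.integers(0, chromsizes["chr1"] - 20_000, size=4))
    bedpe_rows.append(("chr1", int(extra_anchors[0]), int(extra_anchors[0]) + 5000,
                       "chr1", int(extra_anchors[1]) + 40_000, int(extra_anchors[1]) + 45_000,
                       "pair_1", "12", "+", "+"))
    bedpe_rows.append(("chr1", int(extra_anchors[2]), int(extra_anchors[2]) + 5000,
                       "chr2", 100_000, 105_000, "pair_2", "7", "-", "+"))
    bedpe_rows.sort(key=lambda r: (r[0], r[1]))
    files["bedpe"] = p("loops.bedpe")
    with open(files["bedpe"], "w") as fh:
        for row in bedpe_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    truth["bedpe"] = [list(r) for r in bedpe_rows]

    # 4DN pairs
    pairs_rows = []
    for k in range(60):
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        pos1 = int(rng.integers(1, chromsizes[chrom] - 1000))
        pos2 = int(rng.integers(1, chromsizes[chrom] - 1000))
        pairs_rows.append((f"read{k}", chrom, min(pos1, pos2), chrom, max(pos1, pos2)))
    pairs_rows.sort(key=lambda r: (r[1], r[2]))
    files["pairs"] = p("contacts.pairs")
    with open(files["pairs"], "w") as fh:
        fh.write("## pairs format v1.0\n#columns: readID chr1 pos1 chr2 pos2\n")
        for row in pairs_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    truth["pairs"] = [list(r) for r in pairs_rows]

    # SNP table
    snp_rows = []
    for chrom in sorted(chromsizes):
        n_snp = 200 if chrom == "chr1" else 100
        poss = np.sort(rng.integers(1, chromsizes[chrom], size=n_snp))
        pvals = 10.0 ** (-rng.uniform(0.05, 8, size=n_snp))
        for pos, pv in zip(poss, pvals):
            snp_rows.append((chrom, int(pos), float(f"{pv:.6g}")))
    files["snp"] = p("snps.tsv")
    with open(files["snp"], "w") as fh:
        fh.write("chrom\tpos\tpvalue\n")
        for chrom, pos, pv in snp_rows:
            fh.write(f"{chrom}\t{pos}\t{pv:.6g}\n")
    truth["snp"] = [list(r) for r in snp_rows]

    manifest = FixtureManifest(
        seed=seed,
        chromsizes=chromsizes,
        resolution=resolution,
        planted_tad_boundaries=[boundary],
        planted_loops=[loop],
        signal_functions={
            "bedgraph": f"uniform(0, 10) per {tile} bp tile, rounded to 3 decimals",
            "matrix": (f"round({DEFAULT_C:g}*exp(-|i-j|/{DEFAULT_DECAY_LENGTH:g}))"
                       f" + {DEFAULT_TAD_BONUS:g}*same_block + loop strength"),
        },
        files=files,
        ground_truth=truth,
    )
    manifest.to_json(p("manifest.json"))
    files["manifest"] = p("manifest.json")
    return manifest
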