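import numpy as np
import pytest

from trackstack import GenomeRange, generate_dataset

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One generated dataset shared by the whole session (read-only)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    manifest = generate_dataset(str(outdir), seed=FIXTURE_SEED)
    return manifest


@pytest.fixture(scope="session")
def matrix_source(dataset):
    return (dataset.files["matrix_bins"], dataset.files["matrix"])


def random_ranges(rng, chromsizes, n, min_len=200, max_len=120_000):
    """Seeded random query ranges over the fixture genome (plus a chrom
    absent from every file, to exercise the empty case)."""
    chroms = sorted(chromsizes) + ["chrU"]
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        size = chromsizes.get(chrom, 100_000)
        length = int(rng.integers(min_len, max_len))
        start = int(rng.integers(1, max(2, size - length)))
        out.append(GenomeRange(chrom, start, start + length - 1))
    return out
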