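import io

import numpy as np
import pytest

from senechip.core import GenomeTable, GenomicInterval, MappedRead
from senechip.windows import WindowGrid, WindowTrack


@pytest.fixture
def genome():
    return GenomeTable({"chrT": 30_000, "chrU": 10_000})


@pytest.fixture
def grid(genome):
    return WindowGrid(genome, 100)


def make_track(grid, **vectors):
    """Track with the given per-chromosome vectors, zero elsewhere."""
    counts = {c: np.zeros(grid.n_windows(c)) for c in grid.genome}
    for chrom, vec in vectors.items():
        counts[chrom][: len(vec)] = vec
    return WindowTrack(grid, counts)


def read(chrom, start, end, strand, name="r"):
    return MappedRead(chrom, start, end, strand, name)


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)
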