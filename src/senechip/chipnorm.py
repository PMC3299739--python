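"""Two-stage differential histone-modification detection.

Given one mark's IP libraries at two conditions (with matched inputs),
stage 1 discards 200-bp bins dominated by stochastic background noise or
local genomic bias; stage 2 quantile-normalizes the retained bins so the
two libraries share one count distribution, labels bins whose
pseudocounted fold change reaches the threshold tau (default 2.0), and
merges same-direction runs into differential regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval
from .windows import WindowGrid, WindowTrack

__all__ = [
    "DiffConfig",
    "DifferentialRegion",
    "BinTable",
    "stage1_filter",
    "quantile_normalize",
    "call_differential_bins",
    "merge_directional",
    "differential_regions",
    "write_differential_bed",
]

HIGHER_IN_A = "higher_in_A"
HIGHER_IN_B = "higher_in_B"


@dataclass(frozen=True)
class DiffConfig:
    """Differential-detection parameters.

    tau: fold-change threshold on pseudocounted normalized counts.
    bin_width: tiling width in bp. stage1_alpha: Poisson significance for
    the background-noise test. c_bias: both inputs above c_bias x their
    genome-wide mean flags a bin as locally biased. use_bias_filter=False
    reproduces a reading of stage 1 that uses the IP libraries only.
    """

    tau: float = 2.0
    bin_width: int = 200
    stage1_alpha: float = 0.01
    pseudocount: float = 1.0
    merge_gap: int = 0
    c_bias: float = 5.0
    use_bias_filter: bool = True

    def __post_init__(self):
        if self.tau <= 1:
            raise ValueError("tau must be > 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass(frozen=True, slots=True)
class DifferentialRegion:
    interval: GenomicInterval
    direction: str
    mean_log2_fold: float
    n_bins: int


@dataclass
class BinTable:
    """Per-bin intermediate state of the two-stage procedure, one grid."""

    grid: WindowGrid
    count_a: dict[str, np.ndarray]
    count_b: dict[str, np.ndarray]
    retained: dict[str, np.ndarray]
    norm_a: dict[str, np.ndarray]  # NaN where not retained
    norm_b: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]  # +1 higher_in_A, -1 higher_in_B, 0 none
    log2_fold: dict[str, np.ndarray]


def _check_same_grid(*tracks: WindowTrack) -> WindowGrid:
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_grid(t):
            raise ValueError("tracks are on different grids")
    return first.grid


def stage1_filter(
    count_a: WindowTrack,
    count_b: WindowTrack,
    input_a: WindowTrack | None,
    input_b: WindowTrack | None,
    config: DiffConfig = DiffConfig(),
) -> dict[str, np.ndarray]:
    """Boolean retained mask per chromosome.

    A bin survives iff at least one IP library's count is significantly
    above that library's genome-wide mean bin count (Poisson upper tail
    < stage1_alpha) — the noise test — and, when inputs are provided and
    the bias filter enabled, the bin is not flagged as locally biased
    (both scaled inputs above c_bias x their genome-wide mean).
    """
    tracks = [count_a, count_b] + [t for t in (input_a, input_b) if t is not None]
    grid = _check_same_grid(*tracks)
    lam_a = max(count_a.mean(), np.finfo(float).tiny)
    lam_b = max(count_b.mean(), np.finfo(float).tiny)
    use_bias = config.use_bias_filter and input_a is not None and input_b is not None
    if use_bias:
        mean_ia = input_a.mean()
        mean_ib = input_b.mean()
    retained = {}
    for chrom in grid.genome:
        ka = np.rint(count_a.counts[chrom]).astype(np.int64)
        kb = np.rint(count_b.counts[chrom]).astype(np.int64)
        above = (stats.poisson.sf(ka - 1, lam_a) < config.stage1_alpha) | (
            stats.poisson.sf(kb - 1, lam_b) < config.stage1_alpha
        )
        keep = above
        if use_bias:
            biased = (input_a.counts[chrom] > config.c_bias * mean_ia) & (
                input_b.counts[chrom] > config.c_bias * mean_ib
            )
            keep = keep & ~biased
        retained[chrom] = keep
    return retained


def quantile_normalize(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample quantile normalization by rank-wise mapping.

    The reference distribution is the element-wise mean of the two sorted
    vectors; each value is replaced by the reference value at its rank,
    ties receiving the mean of the reference over the tied ranks. For
    tie-free inputs the sorted outputs of the two vectors are identical.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size == 0:
        raise ValueError("inputs must be non-empty")
    ref = (np.sort(a) + np.sort(b)) / 2.0
    return _map_to_ref(a, ref), _map_to_ref(b, ref)


def _map_to_ref(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    # average reference values over tied ranks
    order = np.argsort(x, kind="stable")
    out = np.empty_like(ref)
    sorted_x = x[order]
    i = 0
    n = x.size
    while i < n:
        j = i
        while j + 1 < n and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        out[i : j + 1] = ref[i : j + 1].mean()
        i = j + 1
    result = np.empty_like(out)
    result[order] = out
    return result


def call_differential_bins(
    a_norm: np.ndarray, b_norm: np.ndarray, config: DiffConfig = DiffConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Label bins by pseudocounted fold change.

    Returns (labels, log2_fold): label +1 where (a+pc)/(b+pc) >= tau,
    -1 where (b+pc)/(a+pc) >= tau, else 0.
    """
    pc = config.pseudocount
    ratio = (np.asarray(a_norm, dtype=float) + pc) / (np.asarray(b_norm, dtype=float) + pc)
    labels = np.zeros(ratio.shape, dtype=np.int8)
    labels[ratio >= config.tau] = 1
    labels[1.0 / ratio >= config.tau] = -1
    return labels, np.log2(ratio)


def merge_directional(
    labels: dict[str, np.ndarray],
    grid: WindowGrid,
    log2_fold: dict[str, np.ndarray],
    merge_gap: int = 0,
) -> list[DifferentialRegion]:
    """Merge maximal same-direction runs of labeled bins.

    Opposite directions never merge; runs of one direction separated by
    <= merge_gap unlabeled bins coalesce. mean_log2_fold is the mean of
    the constituent labeled bins' log2 ratios.
    """
    regions: list[DifferentialRegion] = []
    for chrom in grid.genome:
        lab = labels[chrom]
        lf = log2_fold[chrom]
        for direction in (1, -1):
            idx = np.nonzero(lab == direction)[0]
            if idx.size == 0:
                continue
            run_start = idx[0]
            prev = idx[0]
            for i in idx[1:]:
                gap = lab[prev + 1 : i]
                # a bin of the opposite direction always breaks the run
                if i - prev - 1 > merge_gap or np.any(gap == -direction):
                    regions.append(_make_diff_region(grid, chrom, lab, lf, direction, run_start, prev))
                    run_start = i
                prev = i
            regions.append(_make_diff_region(grid, chrom, lab, lf, direction, run_start, prev))
    regions.sort(key=lambda r: (list(grid.genome.chroms).index(r.interval.chrom), r.interval.start))
    return regions


def _make_diff_region(grid, chrom, lab, lf, direction, first, last) -> DifferentialRegion:
    in_run = lab[first : last + 1] == direction
    folds = lf[first : last + 1][in_run]
    start = int(first) * grid.width
    end = min((int(last) + 1) * grid.width, grid.genome[chrom])
    return DifferentialRegion(
        GenomicInterval(chrom, start, end),
        HIGHER_IN_A if direction == 1 else HIGHER_IN_B,
        float(folds.mean()),
        int(in_run.sum()),
    )


def differential_regions(
    count_a: WindowTrack,
    count_b: WindowTrack,
    input_a: WindowTrack | None = None,
    input_b: WindowTrack | None = None,
    config: DiffConfig = DiffConfig(),
) -> tuple[list[DifferentialRegion], BinTable]:
    """Run the full two-stage procedure on 200-bp count tracks."""
    grid = _check_same_grid(count_a, count_b)
    retained = stage1_filter(count_a, count_b, input_a, input_b, config)
    flat_a = np.concatenate([count_a.counts[c][retained[c]] for c in grid.genome])
    flat_b = np.concatenate([count_b.counts[c][retained[c]] for c in grid.genome])
    labels = {c: np.zeros(retained[c].size, dtype=np.int8) for c in grid.genome}
    log2_fold = {c: np.zeros(retained[c].size) for c in grid.genome}
    norm_a = {c: np.full(retained[c].size, np.nan) for c in grid.genome}
    norm_b = {c: np.full(retained[c].size, np.nan) for c in grid.genome}
    if flat_a.size:
        na, nb = quantile_normalize(flat_a, flat_b)
        flat_labels, flat_fold = call_differential_bins(na, nb, config)
        offset = 0
        for chrom in grid.genome:
            m = retained[chrom]
            k = int(m.sum())
            labels[chrom][m] = flat_labels[offset : offset + k]
            log2_fold[chrom][m] = flat_fold[offset : offset + k]
            norm_a[chrom][m] = na[offset : offset + k]
            norm_b[chrom][m] = nb[offset : offset + k]
            offset += k
    regions = merge_directional(labels, grid, log2_fold, config.merge_gap)
    table = BinTable(grid, count_a.counts, count_b.counts, retained,
                     norm_a, norm_b, labels, log2_fold)
    return regions, table


def write_differential_bed(regions: Sequence[DifferentialRegion], dest) -> None:
    """BED9 with the browser colour convention: red = higher in condition
    A (mature, 23 d), green = higher in condition B (senescent, 52 d)."""
    stream = open(dest, "wt") if isinstance(dest, (str, Path)) else dest
    for r in regions:
        rgb = "255,0,0" if r.direction == HIGHER_IN_A else "0,160,0"
        score = int(round(100 * abs(r.mean_log2_fold)))
        iv = r.interval
        stream.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.direction}\t{min(score, 1000)}\t.\t"
            f"{iv.start}\t{iv.end}\t{rgb}\n"
        )
    if isinstance(dest, (str, Path)):
        stream.close()
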