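"""Per-gene integration of histone-mark calls with expression.

Assigns peak and differential-region evidence to genes, classifies the
four-way per-mark state across the two conditions (e.g. K4-K4, K4-None,
None-K4, None-None), classifies transitions of genes bivalent at the
first condition, partitions genes into equal expression-change quintiles
(group A = most down between conditions, E = most up), cross-tabulates
state by group, builds TSS-relative histograms of differential regions,
and applies simple fold-change filters to qPCR-style tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calling import PeakRegion, presence_call
from .chipnorm import HIGHER_IN_A, HIGHER_IN_B, DifferentialRegion
from .core import GenomeTable, GenomicInterval, GeneModel, overlap_length

__all__ = [
    "GeneMarkState",
    "TssBinHistogram",
    "gene_territory",
    "classify_state",
    "classify_bivalent_transition",
    "assign_states",
    "partition_expression_groups",
    "crosstab_states_by_group",
    "assign_diff_regions_to_tss_bins",
    "fold_change_filter",
    "load_expression_table",
    "load_qpcr_table",
    "BIVALENT_CATEGORIES",
]

GROUP_LABELS = "ABCDE"
BIVALENT_CATEGORIES = ("lost_both", "retained_K27", "retained_K4", "retained_both")


@dataclass(frozen=True, slots=True)
class GeneMarkState:
    """Presence of one mark on one gene at the two conditions."""

    gene_id: str
    mark: str
    present_a: bool
    present_b: bool
    category: str
    diff_supported: bool = False


@dataclass
class TssBinHistogram:
    """Counts of differential regions in 200-bp TSS-relative bins.

    Bin +1 covers [TSS, TSS+width); bin -1 the width immediately
    upstream; there is no bin 0. Regions with no gene TSS within the
    horizon are tallied as unassigned.
    """

    mark: str
    width: int
    counts: dict[int, int]
    unassigned: int

    def to_frame(self) -> pd.DataFrame:
        bins = sorted(self.counts)
        return pd.DataFrame({"bin": bins, "count": [self.counts[b] for b in bins]})


def gene_territory(gene: GeneModel, genome: GenomeTable, upstream: int = 500) -> GenomicInterval:
    """Strand-aware territory from (TSS - upstream) to the TES, clipped.

    One territory serves both marks: it covers the promoter-proximal zone
    where H3K4me3 peaks sit and the gene body where H3K27me3 spreads.
    """
    iv = gene.interval
    if gene.strand == "+":
        start, end = iv.start - upstream, iv.end
    else:
        start, end = iv.start, iv.end + upstream
    start = max(0, start)
    end = min(genome[gene.chrom], end)
    return GenomicInterval(gene.chrom, start, end)


def classify_state(present_a: bool, present_b: bool, mark: str) -> str:
    """Four-way category from per-condition presence, e.g. K4-None."""
    a = mark if present_a else "None"
    b = mark if present_b else "None"
    return f"{a}-{b}"


def classify_bivalent_transition(k4_state: GeneMarkState, k27_state: GeneMarkState) -> str:
    """Transition category for a gene bivalent at condition A.

    From condition-B presence: neither mark -> lost_both; K27 only ->
    retained_K27; K4 only -> retained_K4; both -> retained_both.
    """
    if not (k4_state.present_a and k27_state.present_a):
        raise ValueError(f"gene {k4_state.gene_id} is not bivalent at condition A")
    if k4_state.gene_id != k27_state.gene_id:
        raise ValueError("states describe different genes")
    match (k4_state.present_b, k27_state.present_b):
        case (False, False):
            return "lost_both"
        case (False, True):
            return "retained_K27"
        case (True, False):
            return "retained_K4"
        case _:
            return "retained_both"


def _regions_by_chrom(regions: Sequence) -> dict[str, list]:
    by: dict[str, list] = {}
    for r in regions:
        by.setdefault(r.interval.chrom, []).append(r)
    return by


def assign_states(
    genes: Sequence[GeneModel],
    peaks_a: Sequence[PeakRegion],
    peaks_b: Sequence[PeakRegion],
    mark: str,
    genome: GenomeTable,
    diff_regions: Sequence[DifferentialRegion] = (),
    upstream: int = 500,
) -> list[GeneMarkState]:
    """Per-gene mark state from the two conditions' peak calls.

    diff_supported records, for the two asymmetric categories, whether a
    direction-consistent differential region (higher_in_A for MARK-None,
    higher_in_B for None-MARK) overlaps the gene territory.
    """
    pa = _regions_by_chrom(peaks_a)
    pb = _regions_by_chrom(peaks_b)
    dr = _regions_by_chrom(diff_regions)
    states = []
    for gene in genes:
        terr = gene_territory(gene, genome, upstream)
        present_a = presence_call(gene, pa.get(gene.chrom, ()), terr)
        present_b = presence_call(gene, pb.get(gene.chrom, ()), terr)
        supported = False
        if present_a != present_b:
            want = HIGHER_IN_A if present_a else HIGHER_IN_B
            supported = any(
                r.direction == want and overlap_length(r.interval, terr) >= 1
                for r in dr.get(gene.chrom, ())
            )
        states.append(
            GeneMarkState(
                gene.gene_id, mark, present_a, present_b,
                classify_state(present_a, present_b, mark), supported,
            )
        )
    return states


def partition_expression_groups(
    records: pd.DataFrame, n_groups: int = 5, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Partition genes into equal-size groups by expression log-ratio.

    Ranks by log2((expr_b + pc)/(expr_a + pc)), gene_id breaking ties, and
    assigns contiguous blocks (sizes differing by at most 1) to groups
    A..E in rank order: group A holds the genes most down-regulated at
    condition B, group E the most up-regulated.
    """
    required = {"gene_id", "expr_a", "expr_b"}
    if not required.issubset(records.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    n = len(records)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} records, got {n}")
    if (records["expr_a"] < 0).any() or (records["expr_b"] < 0).any():
        raise ValueError("expressions must be non-negative")
    out = records.copy()
    out["log_ratio"] = np.log2((out["expr_b"] + pseudocount) / (out["expr_a"] + pseudocount))
    out = out.sort_values(["log_ratio", "gene_id"], kind="stable").reset_index(drop=True)
    base, extra = divmod(n, n_groups)
    sizes = [base + (1 if i < extra else 0) for i in range(n_groups)]
    labels = []
    for i, size in enumerate(sizes):
        labels.extend(GROUP_LABELS[i] * size)
    out["group"] = labels
    return out


def crosstab_states_by_group(
    states: Sequence[GeneMarkState], records: pd.DataFrame, mark: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group x category counts and per-group proportions.

    Every state's gene must appear in the grouped expression records;
    unmatched genes are reported together in the error.
    """
    if "group" not in records.columns:
        raise ValueError("records must carry a 'group' column (partition first)")
    by_gene = dict(zip(records["gene_id"], records["group"]))
    missing = [s.gene_id for s in states if s.mark == mark and s.gene_id not in by_gene]
    if missing:
        raise ValueError(f"gene_ids missing from expression records: {missing}")
    categories = [
        classify_state(a, b, mark) for a, b in ((True, True), (True, False), (False, True), (False, False))
    ]
    groups = sorted(set(records["group"]))
    counts = pd.DataFrame(0, index=groups, columns=categories, dtype=int)
    for s in states:
        if s.mark != mark:
            continue
        counts.loc[by_gene[s.gene_id], s.category] += 1
    group_sizes = counts.sum(axis=1)
    proportions = counts.div(group_sizes.replace(0, np.nan), axis=0).fillna(0.0)
    return counts, proportions


def assign_diff_regions_to_tss_bins(
    regions: Sequence[DifferentialRegion],
    genes: Sequence[GeneModel],
    mark: str = "",
    bin_width: int = 200,
    horizon: int = 10_000,
) -> TssBinHistogram:
    """Histogram of differential regions in TSS-relative bins.

    Each region goes, by its midpoint, to the nearest gene TSS within the
    horizon; the bin index is strand-aware (downstream positive, bin +1 =
    [TSS, TSS+width)). Regions with no TSS in range count as unassigned.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_sorted = {
        c: sorted(gs, key=lambda g: (g.tss, g.gene_id)) for c, gs in by_chrom.items()
    }
    tss_pos = {c: np.array([g.tss for g in gs]) for c, gs in tss_sorted.items()}
    counts: dict[int, int] = {}
    unassigned = 0
    for r in regions:
        mid = (r.interval.start + r.interval.end) // 2
        gs = tss_sorted.get(r.interval.chrom)
        if not gs:
            unassigned += 1
            continue
        pos = tss_pos[r.interval.chrom]
        i = int(np.searchsorted(pos, mid))
        candidates = [j for j in (i - 1, i) if 0 <= j < len(gs)]
        best = min(candidates, key=lambda j: (abs(mid - pos[j]), gs[j].gene_id))
        gene = gs[best]
        dist = mid - gene.tss if gene.strand == "+" else gene.tss - mid
        if abs(mid - gene.tss) > horizon:
            unassigned += 1
            continue
        idx = math.floor(dist / bin_width)
        bin_index = idx + 1 if idx >= 0 else idx
        counts[bin_index] = counts.get(bin_index, 0) + 1
    return TssBinHistogram(mark=mark, width=bin_width, counts=counts, unassigned=unassigned)


def fold_change_filter(folds: Iterable[float], threshold: float) -> int:
    """Number of fold values >= threshold (inclusive).

    Folds must be positive: fold-up for up-regulated genes is
    expr_b/expr_a, fold-down for down-regulated genes is expr_a/expr_b.
    """
    count = 0
    for f in folds:
        if f <= 0:
            raise ValueError(f"fold values must be positive, got {f}")
        if f >= threshold:
            count += 1
    return count


def load_expression_table(source) -> pd.DataFrame:
    """TSV with header gene_id, expr_a, expr_b."""
    df = pd.read_csv(source, sep="\t")
    required = {"gene_id", "expr_a", "expr_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    return df


def load_qpcr_table() -> pd.DataFrame:
    """Bundled qPCR fold table of tested senescence up-/down-regulated
    genes (SURG/SDRG), relative mRNA levels at 23 d and 52 d.

    Returns columns gene_id, set (SURG/SDRG), expr_23d, expr_52d, fold
    (fold-up at 52 d for SURGs, fold-down at 52 d for SDRGs).
    """
    ref = resources.files("senechip").joinpath("data/senescence_qpcr.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    up = df["set"] == "SURG"
    df["fold"] = np.where(up, df["expr_52d"] / df["expr_23d"], df["expr_23d"] / df["expr_52d"])
    return df
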