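"""Synthetic ChIP-seq experiment generator with planted truth.

Emits a small genome, a non-overlapping gene annotation, per-gene
H3K4me3/H3K27me3 state pairs at two conditions (A = mature, B =
senescent), an expression table whose up/down structure is coupled to
mark gains and losses, and BED6 read sets for the IP and input
libraries of both conditions, all deterministic given one seed.

Reads are placed by an inhomogeneous Poisson process: the input
libraries are uniform background; an IP library is elevated by
``enrichment_fold`` over intervals where its mark is present
(promoter-proximal [TSS, TSS+1 kb) for K4-like marks, the gene body for
K27-like marks). A gene whose mark is present at only one condition
keeps a residual ``enrichment_fold / differential_fold`` elevation at
the other condition, so the planted between-condition fold equals
``differential_fold`` while the residual stays below the presence
threshold. The truth table records planted states, enriched intervals,
and directional differential intervals for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chipnorm import HIGHER_IN_A, HIGHER_IN_B
from .core import (
    GenomeTable,
    GenomicInterval,
    GeneModel,
    MappedRead,
    write_chrom_sizes,
    write_genes_gff3,
    write_reads,
)

__all__ = ["SimConfig", "TruthTable", "SimResult", "simulate_annotation",
           "simulate_states_and_expression", "simulate_reads", "simulate_input_reads",
           "simulate_experiment"]

STATES = ("both", "none", "a_only", "b_only")
LIBRARIES = ("K4_ip_a", "K4_ip_b", "K27_ip_a", "K27_ip_b", "input_a", "input_b")


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiment.

    background_rate is the read-start density (reads per bp per
    library); the default 0.007 yields an expected ~2 fragments per
    100-bp window once 36-bp reads are extended by 150 bp
    (0.007 x (185 + 100 - 1) ~= 2). State proportions follow the
    genome-wide pattern of the real tissue comparison: most genes keep
    K4 at both stages or at neither (~60%/~35%), and ~90% of genes never
    carry K27.
    """

    seed: int
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 400
    gene_length: tuple[int, int] = (1_000, 4_000)
    k4_proportions: dict = field(
        default_factory=lambda: {"both": 0.60, "none": 0.35, "a_only": 0.025, "b_only": 0.025}
    )
    k27_proportions: dict = field(
        default_factory=lambda: {"none": 0.90, "both": 0.04, "a_only": 0.05, "b_only": 0.01}
    )
    enrichment_fold: float = 8.0
    differential_fold: float = 4.0
    background_rate: float = 0.007
    expression_effect: float = 2.0
    expression_noise_sd: float = 0.5
    read_length: int = 36
    k4_domain: int = 1_000
    intergenic_spacing: int = 2_000
    duplication_rate: float = 0.0
    n_bias_regions: int = 0
    bias_fold: float = 8.0
    bias_length: int = 2_000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, props in (("k4", self.k4_proportions), ("k27", self.k27_proportions)):
            if set(props) != set(STATES):
                raise ValueError(f"{name}_proportions must have keys {STATES}")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}_proportions must sum to 1")
        for rate in (self.background_rate, self.enrichment_fold, self.differential_fold):
            if rate <= 0:
                raise ValueError("rates and folds must be positive")


@dataclass
class TruthTable:
    """Planted ground truth: per-gene states, enriched intervals, and
    directional differential intervals."""

    genes: pd.DataFrame        # gene_id, chrom, start, end, strand, tss, k4_state, k27_state, expr_tendency
    intervals: pd.DataFrame    # mark, condition, chrom, start, end, fold, gene_id, kind (enriched|residual)
    differentials: pd.DataFrame  # mark, chrom, start, end, direction, true_fold, gene_id

    def enriched_intervals(self, mark: str, condition: str, full_only: bool = True) -> list[GenomicInterval]:
        df = self.intervals
        sel = (df["mark"] == mark) & (df["condition"] == condition)
        if full_only:
            sel &= df["kind"] == "enriched"
        return [GenomicInterval(r.chrom, r.start, r.end) for r in df[sel].itertuples()]

    def differential_regions(self, mark: str) -> list[tuple[GenomicInterval, str]]:
        df = self.differentials
        return [
            (GenomicInterval(r.chrom, r.start, r.end), r.direction)
            for r in df[df["mark"] == mark].itertuples()
        ]

    def state_of(self, mark: str) -> pd.Series:
        return self.genes.set_index("gene_id")[f"{mark.lower()}_state"]


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeTable
    genes: list[GeneModel]
    truth: TruthTable
    expression: pd.DataFrame
    reads: dict[str, list[MappedRead]]


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_annotation(config: SimConfig) -> tuple[GenomeTable, list[GeneModel]]:
    """Place non-overlapping genes with random strands and a minimum
    intergenic spacing, uniformly via random gap allocation."""
    rng = _rngs(config.seed, 8)[0]
    genome = GenomeTable(
        [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)]
    )
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gid = 0
    lo, hi = config.gene_length
    for ci, chrom in enumerate(genome):
        k = per_chrom[ci]
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        reserved = int(lengths.sum()) + (k + 1) * config.intergenic_spacing
        free = config.chrom_length - reserved
        if free < 0:
            raise ValueError(
                f"cannot place {k} genes of up to {hi} bp with {config.intergenic_spacing} bp "
                f"spacing on a {config.chrom_length} bp chromosome"
            )
        gaps = np.floor(rng.dirichlet(np.ones(k + 1)) * free).astype(int)
        strands = rng.integers(0, 2, size=k)
        pos = config.intergenic_spacing + int(gaps[0])
        for j in range(k):
            start = pos
            end = start + int(lengths[j])
            strand = "+" if strands[j] == 0 else "-"
            gid += 1
            genes.append(GeneModel(f"g{gid:05d}", GenomicInterval(chrom, start, end, strand)))
            pos = end + config.intergenic_spacing + int(gaps[j + 1])
    return genome, genes


def _downstream_interval(gene: GeneModel, length: int, chrom_len: int) -> GenomicInterval:
    if gene.strand == "+":
        start, end = gene.tss, min(gene.tss + length, chrom_len)
    else:
        start, end = max(0, gene.tss + 1 - length), gene.tss + 1
    return GenomicInterval(gene.chrom, start, end)


def simulate_states_and_expression(
    config: SimConfig, genome: GenomeTable, genes: Sequence[GeneModel]
) -> tuple[TruthTable, pd.DataFrame]:
    """Draw per-gene mark states and a coupled expression table.

    Baseline log2 expression ~ Normal(5, 1) at both conditions; K4 gain
    adds +effect to the condition-B expression and K4 loss subtracts it;
    K27 gain/loss apply the opposite signs; independent Normal(0, sd)
    noise is added per condition and values are exponentiated.
    """
    rng_states, rng_expr = _rngs(config.seed, 8)[1:3]
    n = len(genes)
    k4 = rng_states.choice(STATES, size=n, p=[config.k4_proportions[s] for s in STATES])
    k27 = rng_states.choice(STATES, size=n, p=[config.k27_proportions[s] for s in STATES])
    base = rng_expr.normal(5.0, 1.0, size=n)
    shift = config.expression_effect * (
        (k4 == "b_only").astype(float) - (k4 == "a_only").astype(float)
        - (k27 == "b_only").astype(float) + (k27 == "a_only").astype(float)
    )
    log_a = base + rng_expr.normal(0.0, config.expression_noise_sd, size=n)
    log_b = base + shift + rng_expr.normal(0.0, config.expression_noise_sd, size=n)
    expression = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "expr_a": np.power(2.0, log_a),
            "expr_b": np.power(2.0, log_b),
        }
    )
    tendency = np.where(shift > 0, "up", np.where(shift < 0, "down", "neutral"))
    gene_rows = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "k4_state": k4,
            "k27_state": k27,
            "expr_tendency": tendency,
        }
    )
    intervals, differentials = [], []
    residual_fold = config.enrichment_fold / config.differential_fold
    for g, s4, s27 in zip(genes, k4, k27):
        chrom_len = genome[g.chrom]
        domains = {
            "K4": _downstream_interval(g, config.k4_domain, chrom_len),
            "K27": g.interval,
        }
        for mark, state in (("K4", s4), ("K27", s27)):
            iv = domains[mark]
            if state == "none":
                continue
            for condition in ("a", "b"):
                present = state == "both" or state == f"{condition}_only"
                other_present = state != "none" and not present
                if present:
                    intervals.append((mark, condition, iv.chrom, iv.start, iv.end,
                                      config.enrichment_fold, g.gene_id, "enriched"))
                elif other_present and residual_fold > 1:
                    intervals.append((mark, condition, iv.chrom, iv.start, iv.end,
                                      residual_fold, g.gene_id, "residual"))
            if state in ("a_only", "b_only"):
                direction = HIGHER_IN_A if state == "a_only" else HIGHER_IN_B
                differentials.append((mark, iv.chrom, iv.start, iv.end, direction,
                                      config.differential_fold, g.gene_id))
    truth = TruthTable(
        genes=gene_rows,
        intervals=pd.DataFrame(
            intervals,
            columns=["mark", "condition", "chrom", "start", "end", "fold", "gene_id", "kind"],
        ),
        differentials=pd.DataFrame(
            differentials,
            columns=["mark", "chrom", "start", "end", "direction", "true_fold", "gene_id"],
        ),
    )
    return truth, expression


def _bias_regions(config: SimConfig, genome: GenomeTable) -> list[GenomicInterval]:
    if config.n_bias_regions == 0:
        return []
    rng = _rngs(config.seed, 8)[3]
    out = []
    chroms = genome.chroms
    for _ in range(config.n_bias_regions):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, genome[chrom] - config.bias_length))
        out.append(GenomicInterval(chrom, start, start + config.bias_length))
    return out


def _sample_library(
    rng: np.random.Generator,
    genome: GenomeTable,
    elevated: list[tuple[GenomicInterval, float]],
    config: SimConfig,
    name_prefix: str,
) -> list[MappedRead]:
    """Draw one library's reads from a piecewise-constant start-position
    intensity (background_rate x local fold multiplier)."""
    rl = config.read_length
    reads: list[MappedRead] = []
    idx = 0
    for chrom in genome:
        span = genome[chrom] - rl + 1
        points = {0, span}
        local = [(iv, f) for iv, f in elevated if iv.chrom == chrom]
        for iv, _f in local:
            points.add(min(max(iv.start, 0), span))
            points.add(min(max(iv.end, 0), span))
        bounds = np.array(sorted(points))
        seg_start, seg_end = bounds[:-1], bounds[1:]
        mid = (seg_start + seg_end) / 2.0
        fold = np.ones(mid.size)
        for iv, f in local:
            fold[(mid >= iv.start) & (mid < iv.end)] *= f
        weights = (seg_end - seg_start) * fold
        total = config.background_rate * weights.sum()
        n = int(rng.poisson(total))
        if n == 0:
            continue
        cum = np.cumsum(weights) / weights.sum()
        seg = np.searchsorted(cum, rng.random(n), side="right")
        offs = rng.random(n)
        starts = (seg_start[seg] + np.floor(offs * (seg_end[seg] - seg_start[seg]))).astype(int)
        strands = rng.integers(0, 2, size=n)
        if config.duplication_rate > 0:
            dup = rng.random(n) < config.duplication_rate
            starts = np.concatenate([starts, starts[dup]])
            strands = np.concatenate([strands, strands[dup]])
        order = np.lexsort((strands, starts))
        for s, st in zip(starts[order], strands[order]):
            idx += 1
            reads.append(
                MappedRead(chrom, int(s), int(s) + rl, "+" if st == 0 else "-",
                           f"{name_prefix}{idx:07d}")
            )
    return reads


def simulate_reads(
    config: SimConfig, genome: GenomeTable, truth: TruthTable, mark: str
) -> tuple[list[MappedRead], list[MappedRead]]:
    """IP read libraries (condition A, condition B) for one mark."""
    stream_index = {"K4": 4, "K27": 5}[mark]
    rng_a, rng_b = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(8)[stream_index].spawn(2)
    ]
    bias = [(iv, config.bias_fold) for iv in _bias_regions(config, genome)]
    df = truth.intervals
    out = []
    for condition, rng in (("a", rng_a), ("b", rng_b)):
        sel = df[(df["mark"] == mark) & (df["condition"] == condition)]
        elevated = [
            (GenomicInterval(r.chrom, r.start, r.end), r.fold) for r in sel.itertuples()
        ] + bias
        out.append(_sample_library(rng, genome, elevated, config, f"{mark}{condition}_"))
    return out[0], out[1]


def simulate_input_reads(
    config: SimConfig, genome: GenomeTable, condition: str
) -> list[MappedRead]:
    """One uniform-background input library (plus any bias field)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(8)[6].spawn(2)[0 if condition == "a" else 1]
    )
    bias = [(iv, config.bias_fold) for iv in _bias_regions(config, genome)]
    return _sample_library(rng, genome, bias, config, f"in{condition}_")


def simulate_experiment(config: SimConfig, outdir: "Path | str | None" = None) -> SimResult:
    """Generate the full synthetic experiment; optionally write all files.

    Writes genome.tsv, genes.gff3, expression.tsv, truth_genes.tsv,
    truth_intervals.tsv, truth_differentials.tsv and six BED6 read sets
    (K4/K27 IP at both conditions, two inputs).
    """
    genome, genes = simulate_annotation(config)
    truth, expression = simulate_states_and_expression(config, genome, genes)
    reads = {}
    reads["K4_ip_a"], reads["K4_ip_b"] = simulate_reads(config, genome, truth, "K4")
    reads["K27_ip_a"], reads["K27_ip_b"] = simulate_reads(config, genome, truth, "K27")
    reads["input_a"] = simulate_input_reads(config, genome, "a")
    reads["input_b"] = simulate_input_reads(config, genome, "b")
    result = SimResult(config, genome, genes, truth, expression, reads)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(genome, outdir / "genome.tsv")
        write_genes_gff3(genes, outdir / "genes.gff3")
        expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        truth.intervals.to_csv(outdir / "truth_intervals.tsv", sep="\t", index=False)
        truth.differentials.to_csv(outdir / "truth_differentials.tsv", sep="\t", index=False)
        for lib, rs in reads.items():
            write_reads(rs, outdir / f"{lib}.bed")
    return result
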