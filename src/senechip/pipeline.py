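"""End-to-end pipeline: from mapped reads to per-gene state tables.

Stages, in order: window count tracks per library; per-mark,
per-condition Poisson peak calling against scaled input; empirical FDR
from the input-vs-input comparison; per-mark two-stage differential
regions at 200 bp; per-gene state classification, bivalency
transitions, expression quintiles, crosstabs and TSS histograms; and a
machine-readable run manifest (parameters + checksums) that suffices to
re-run the pipeline bit-identically on the same inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import calling, chipnorm, integrate, windows
from .calling import CallingConfig
from .chipnorm import DiffConfig
from .core import GenomeTable, load_chrom_sizes, load_genes, load_reads

log = logging.getLogger("senechip")

READ_KEYS = ("k4_ip_a", "k4_ip_b", "k27_ip_a", "k27_ip_b", "input_a", "input_b")
MARK_OF = {"k4": "K4", "k27": "K27"}


@dataclass
class IntegrationConfig:
    territory_upstream: int = 500
    n_groups: int = 5
    expression_pseudocount: float = 1.0
    horizon: int = 10_000
    flank: int = 10_000


@dataclass
class PipelineConfig:
    """Fully resolved pipeline configuration; defaults match the published
    analysis (window 100, extension 150, alpha 1e-6, bin 200, tau 2.0,
    flank 10000, five expression groups)."""

    genome: str
    genes: str
    reads: dict
    expression: "str | None" = None
    outdir: str = "senechip_out"
    seed: int = 0
    log_level: str = "INFO"
    calling: CallingConfig = field(default_factory=CallingConfig)
    diff: DiffConfig = field(default_factory=DiffConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


_SECTION_TYPES = {"calling": CallingConfig, "diff": DiffConfig, "integration": IntegrationConfig}
_TOP_KEYS = {"genome", "genes", "reads", "expression", "outdir", "seed", "log_level",
             "calling", "diff", "integration"}


def validate_config(source) -> PipelineConfig:
    """Build a PipelineConfig from a YAML document, path, or dict.

    All problems — unknown keys, type errors, missing files — are
    collected and reported together.
    """
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        raw = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = dict(source)
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping of keys to values"])
    errors: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown key: {key}")
    sections = {}
    for name, cls in _SECTION_TYPES.items():
        params = raw.get(name) or {}
        valid = {f for f in cls.__dataclass_fields__}
        for key in params:
            if key not in valid:
                errors.append(f"unknown key: {name}.{key}")
        try:
            sections[name] = cls(**{k: v for k, v in params.items() if k in valid})
        except (TypeError, ValueError) as exc:
            errors.append(f"{name}: {exc}")
    for req in ("genome", "genes", "reads"):
        if req not in raw:
            errors.append(f"missing required key: {req}")
    reads = raw.get("reads") or {}
    if not isinstance(reads, dict):
        errors.append("reads must be a mapping of library name -> BED path")
        reads = {}
    for key in READ_KEYS:
        if key not in reads:
            errors.append(f"missing read library: reads.{key}")
    for key in reads:
        if key not in READ_KEYS:
            errors.append(f"unknown key: reads.{key}")
    for label, path in [("genome", raw.get("genome")), ("genes", raw.get("genes")),
                        ("expression", raw.get("expression"))] + [
                        (f"reads.{k}", v) for k, v in reads.items()]:
        if path is not None and isinstance(path, str) and not Path(path).exists():
            errors.append(f"{label}: file not found: {path}")
    if errors:
        raise ConfigError(sorted(errors))
    return PipelineConfig(
        genome=raw["genome"],
        genes=raw["genes"],
        reads={k: reads[k] for k in READ_KEYS},
        expression=raw.get("expression"),
        outdir=raw.get("outdir", "senechip_out"),
        seed=int(raw.get("seed", 0)),
        log_level=raw.get("log_level", "INFO"),
        **sections,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the report directory."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_chrom_sizes(config.genome)
    genes = load_genes(config.genes, genome)
    reads = {k: load_reads(v, genome) for k, v in config.reads.items()}
    cc, dc, ic = config.calling, config.diff, config.integration

    tracks_dir = outdir / "tracks"
    peaks_dir = outdir / "peaks"
    diff_dir = outdir / "diff"
    integ_dir = outdir / "integration"
    for d in (tracks_dir, peaks_dir, diff_dir, integ_dir):
        d.mkdir(exist_ok=True)

    @_stage("count_tracks")
    def count_tracks():
        grid = windows.WindowGrid(genome, cc.window)
        out = {}
        for lib, rs in reads.items():
            frags = windows.extend_reads(
                windows.deduplicate(rs, cc.dedup_ignore_strand), genome, cc.extension
            )
            out[lib] = windows.count_windows(frags, grid)
            windows.write_bedgraph(out[lib], tracks_dir / f"{lib}.bedgraph")
        return out

    tracks = count_tracks()

    @_stage("callpeaks")
    def callpeaks():
        peaks = {}
        for prefix in ("k4", "k27"):
            for cond in ("a", "b"):
                ip = tracks[f"{prefix}_ip_{cond}"]
                inp = windows.scale_to_total(tracks[f"input_{cond}"], ip.library_total)
                lam = calling.expected_track(inp)
                calls = calling.call_windows(ip, lam, cc)
                regs = calling.merge_significant(calls, cc.merge_gap)
                peaks[(MARK_OF[prefix], cond)] = regs
                calling.write_peaks_bed(regs, peaks_dir / f"{MARK_OF[prefix]}_{cond}.bed")
        return peaks

    peaks = callpeaks()

    @_stage("empirical_fdr")
    def fdr_stage():
        ia = tracks["input_a"]
        ib = windows.scale_to_total(tracks["input_b"], ia.library_total)
        lam = calling.expected_track(ib)
        null_regs = calling.merge_significant(calling.call_windows(ia, lam, cc), cc.merge_gap)
        estimates = {}
        for (mark, cond), regs in peaks.items():
            estimates[f"{mark}_{cond}"] = (
                calling.empirical_fdr(len(null_regs), len(regs)) if regs else None
            )
        payload = {"null_peaks": len(null_regs), "fdr": estimates}
        (outdir / "fdr.json").write_text(json.dumps(payload, indent=2) + "\n")
        return payload

    fdr = fdr_stage()

    @_stage("differential")
    def differential():
        grid200 = windows.WindowGrid(genome, dc.bin_width)
        regions = {}
        for prefix in ("k4", "k27"):
            tr = {}
            for lib in (f"{prefix}_ip_a", f"{prefix}_ip_b", "input_a", "input_b"):
                frags = windows.extend_reads(
                    windows.deduplicate(reads[lib], cc.dedup_ignore_strand), genome, cc.extension
                )
                tr[lib] = windows.count_windows(frags, grid200)
            ina = windows.scale_to_total(tr["input_a"], tr[f"{prefix}_ip_a"].library_total)
            inb = windows.scale_to_total(tr["input_b"], tr[f"{prefix}_ip_b"].library_total)
            regs, _ = chipnorm.differential_regions(
                tr[f"{prefix}_ip_a"], tr[f"{prefix}_ip_b"], ina, inb, dc
            )
            regions[MARK_OF[prefix]] = regs
            chipnorm.write_differential_bed(regs, diff_dir / f"{MARK_OF[prefix]}_diff.bed")
        return regions

    diff_regions = differential()

    @_stage("integration")
    def integration():
        states = {}
        for mark in ("K4", "K27"):
            states[mark] = integrate.assign_states(
                genes, peaks[(mark, "a")], peaks[(mark, "b")], mark, genome,
                diff_regions[mark], ic.territory_upstream,
            )
        rows = [asdict(s) for mark in states for s in states[mark]]
        pd.DataFrame(rows).to_csv(integ_dir / "states.tsv", sep="\t", index=False)

        k4_by_gene = {s.gene_id: s for s in states["K4"]}
        k27_by_gene = {s.gene_id: s for s in states["K27"]}
        biv_rows = []
        for gid, s4 in k4_by_gene.items():
            s27 = k27_by_gene[gid]
            if s4.present_a and s27.present_a:
                biv_rows.append(
                    {"gene_id": gid, "transition": integrate.classify_bivalent_transition(s4, s27)}
                )
        pd.DataFrame(biv_rows, columns=["gene_id", "transition"]).to_csv(
            integ_dir / "bivalency.tsv", sep="\t", index=False
        )

        for mark in ("K4", "K27"):
            hist = integrate.assign_diff_regions_to_tss_bins(
                diff_regions[mark], genes, mark, dc.bin_width, ic.horizon
            )
            hist.to_frame().to_csv(integ_dir / f"tss_hist_{mark}.tsv", sep="\t", index=False)

        if config.expression is None:
            log.warning("no expression table; skipping grouping and crosstab stages")
            return states
        records = integrate.partition_expression_groups(
            integrate.load_expression_table(config.expression),
            ic.n_groups, ic.expression_pseudocount,
        )
        records.to_csv(integ_dir / "expression_groups.tsv", sep="\t", index=False)
        for mark in ("K4", "K27"):
            counts, props = integrate.crosstab_states_by_group(states[mark], records, mark)
            counts.to_csv(integ_dir / f"crosstab_{mark}_counts.tsv", sep="\t")
            props.to_csv(integ_dir / f"crosstab_{mark}_proportions.tsv", sep="\t")
        return states

    integration()

    manifest = {
        "parameters": {
            "calling": asdict(cc),
            "diff": asdict(dc),
            "integration": asdict(ic),
            "seed": config.seed,
        },
        "inputs": {
            label: _sha256(Path(path))
            for label, path in [("genome", config.genome), ("genes", config.genes)]
            + [(k, v) for k, v in config.reads.items()]
            + ([("expression", config.expression)] if config.expression else [])
        },
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
        "fdr": fdr,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
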