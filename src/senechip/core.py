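"""Core genomic types and I/O.

All coordinates are 0-based, half-open (BED convention). GFF3's 1-based
closed coordinates are converted at the I/O boundary and never appear
internally. Every interval is validated against a :class:`GenomeTable`
listing chromosome lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "GenomeTable",
    "GenomicInterval",
    "MappedRead",
    "GeneModel",
    "load_chrom_sizes",
    "write_chrom_sizes",
    "load_reads",
    "write_reads",
    "load_genes",
    "write_genes_gff3",
    "overlap_length",
]

STRANDS = ("+", "-")


def _as_text_stream(source) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "rt")
    if isinstance(source, str):
        return io.StringIO(source)
    return source


class GenomeTable:
    """Ordered chromosome name -> length (bp) table.

    Iteration order is the input order; names are unique and lengths
    positive.
    """

    def __init__(self, sizes: "dict[str, int] | Iterable[tuple[str, int]]"):
        items = sizes.items() if isinstance(sizes, dict) else sizes
        self._sizes: dict[str, int] = {}
        for name, length in items:
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if not isinstance(length, (int,)) or isinstance(length, bool):
                raise ValueError(f"chromosome length must be an integer: {length!r}")
            if length < 1:
                raise ValueError(f"chromosome length must be >= 1: {name} {length}")
            self._sizes[name] = int(length)
        if not self._sizes:
            raise ValueError("empty genome table")

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeTable) and list(self.items()) == list(other.items())

    def __repr__(self) -> str:
        return f"GenomeTable({self._sizes!r})"

    @property
    def chroms(self) -> list[str]:
        return list(self._sizes)

    def items(self):
        return self._sizes.items()

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def validate(self, genome: GenomeTable) -> "GenomicInterval":
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:[{self.start},{self.end}) exceeds "
                f"chromosome length {genome[self.chrom]}"
            )
        return self


@dataclass(frozen=True, slots=True)
class MappedRead:
    """A uniquely mapped, strand-aware sequencing read location."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")
        if self.start < 0 or self.end - self.start < 1:
            raise ValueError(f"invalid read [{self.start},{self.end})")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with a strand-aware transcription start (TSS) and end (TES).

    TSS is the 5' end: ``start`` on the + strand, ``end - 1`` on the −
    strand (both as 0-based positions).
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


def load_chrom_sizes(source) -> GenomeTable:
    """Parse a two-column (name, length) whitespace-delimited table."""
    stream = _as_text_stream(source)
    entries: list[tuple[str, int]] = []
    for lineno, line in enumerate(stream, 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected 'name length'")
        name = parts[0]
        try:
            length = int(parts[1])
        except ValueError:
            raise ValueError(f"line {lineno}: non-integer length {parts[1]!r}") from None
        entries.append((name, length))
    if not entries:
        raise ValueError("empty chromosome sizes input")
    return GenomeTable(entries)


def write_chrom_sizes(genome: GenomeTable, dest) -> None:
    stream = open(dest, "wt") if isinstance(dest, (str, Path)) else dest
    for name, length in genome.items():
        stream.write(f"{name}\t{length}\n")
    if isinstance(dest, (str, Path)):
        stream.close()


def load_reads(source, genome: GenomeTable) -> list[MappedRead]:
    """Read BED6 records into validated :class:`MappedRead` objects.

    Strand is mandatory ('.' rejected: unstranded reads cannot be
    extended); coordinates are checked against the genome.
    """
    stream = _as_text_stream(source)
    reads: list[MappedRead] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"line {lineno}: BED6 requires 6 columns")
        chrom, start_s, end_s, name, _score, strand = parts[:6]
        start, end = int(start_s), int(end_s)
        if strand not in STRANDS:
            raise ValueError(f"line {lineno}: read strand must be + or -, got {strand!r}")
        if chrom not in genome:
            raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
        if start >= end:
            raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
        if start < 0 or end > genome[chrom]:
            raise ValueError(
                f"line {lineno}: [{start},{end}) outside chromosome "
                f"{chrom} of length {genome[chrom]}"
            )
        reads.append(MappedRead(chrom, start, end, strand, name))
    return reads


def write_reads(reads: Iterable[MappedRead], dest) -> None:
    """Write reads as BED6 (no header, tab-delimited, newline-terminated)."""
    stream = open(dest, "wt") if isinstance(dest, (str, Path)) else dest
    for r in reads:
        stream.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")
    if isinstance(dest, (str, Path)):
        stream.close()


def load_genes(
    source,
    genome: GenomeTable,
    feature_types: Sequence[str] = ("gene",),
) -> list[GeneModel]:
    """Load gene models from GFF3, keeping features of the given types.

    GFF3 coordinates (1-based, closed) are converted to the internal
    0-based half-open convention. The ID attribute is the gene_id.
    """
    from gffutils.iterators import DataIterator

    if isinstance(source, Path):
        source = str(source)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in DataIterator(source):
        if feat.featuretype not in feature_types:
            continue
        ids = feat.attributes.get("ID") or feat.attributes.get("Name")
        if not ids:
            raise ValueError(f"gene feature without ID at {feat.seqid}:{feat.start}")
        gene_id = ids[0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        iv.validate(genome)
        genes.append(GeneModel(gene_id, iv))
    return genes


def write_genes_gff3(genes: Iterable[GeneModel], dest, source_tag: str = "senechip") -> None:
    stream = open(dest, "wt") if isinstance(dest, (str, Path)) else dest
    stream.write("##gff-version 3\n")
    for g in genes:
        iv = g.interval
        stream.write(
            f"{iv.chrom}\t{source_tag}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\tID={g.gene_id}\n"
        )
    if isinstance(dest, (str, Path)):
        stream.close()


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Intersection length in bp under half-open semantics (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))
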