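"""Genomic intervals, annotation records and interval indexing.

All internal coordinates are 0-based half-open (BED convention).  GFF3 input
(1-based closed) is converted on read and back on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two non-overlapping intervals (0 if they touch
        or overlap); intervals on different chromosomes have no defined gap."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass
class GeneRecord:
    """A gene model: exons on one strand with a biotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str  # protein_coding | lncRNA | other
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


class AnnotationIndex:
    """Interval index over gene and exon records supporting stranded queries."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes: list[GeneRecord] = list(genes)
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._gene_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g
            )
            exons = g.exons or [(g.start, g.end)]
            for (s, e) in exons:
                self._exon_trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g)

    def __len__(self) -> int:
        return len(self.genes)

    def _query(
        self, trees: dict[str, IntervalTree], iv: GenomicInterval, strand: str | None
    ) -> list[GeneRecord]:
        tree = trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        # deduplicate (a gene can contribute several exons) preserving order
        seen: set[str] = set()
        out = []
        for g in hits:
            if g.gene_id not in seen:
                seen.add(g.gene_id)
                out.append(g)
        return out

    def genes_overlapping(
        self, iv: GenomicInterval, strand: str | None = None
    ) -> list[GeneRecord]:
        """Genes whose full extent overlaps `iv` (optionally on `strand`)."""
        return self._query(self._gene_trees, iv, strand)

    def exons_overlapping(
        self, iv: GenomicInterval, strand: str | None = None, biotype: str | None = None
    ) -> list[GeneRecord]:
        hits = self._query(self._exon_trees, iv, strand)
        if biotype is not None:
            hits = [g for g in hits if g.biotype == biotype]
        return hits


def merge_intervals(
    intervals: Iterable[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int]]:
    """Merge intervals whose gap is <= max_gap; output disjoint and sorted."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - out[-1][1] <= max_gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def read_gff3_genes(path: str) -> list[GeneRecord]:
    """Read gene models (gene + exon features) from a GFF3 file.

    Only `gene` and `exon` rows are used; gene_id and biotype are taken from
    the attribute column (`ID=`/`gene_id=` and `biotype=`/`gene_type=`).
    """
    genes: dict[str, GeneRecord] = {}
    exon_buffer: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID") or attr.get("gene_id")
                genes[gid] = GeneRecord(
                    gene_id=gid,
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    biotype=attr.get("biotype", attr.get("gene_type", "other")),
                )
            elif ftype == "exon":
                gid = attr.get("Parent") or attr.get("gene_id")
                exon_buffer.append((gid, int(start) - 1, int(end)))
    for gid, s, e in exon_buffer:
        if gid in genes:
            genes[gid].exons.append((s, e))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values())


def write_gff3_genes(genes: Iterable[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tkmersig\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
            for i, (s, e) in enumerate(g.exons or [(g.start, g.end)], 1):
                fh.write(
                    f"{g.chrom}\tkmersig\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


@dataclass
class Bed12Record:
    """A BED12 line: a (possibly spliced) alignment or transcript structure."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    blocks: list[tuple[int, int]]  # absolute genomic (start, end) per block

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def to_line(self, score: int = 0) -> str:
        sizes = ",".join(str(e - s) for s, e in self.blocks) + ","
        starts = ",".join(str(s - self.start) for s, _ in self.blocks) + ","
        return "\t".join(
            str(x)
            for x in (
                self.chrom,
                self.start,
                self.end,
                self.name,
                score,
                self.strand,
                self.start,
                self.end,
                "0",
                len(self.blocks),
                sizes,
                starts,
            )
        )


def read_bed12(path: str) -> Iterator[Bed12Record]:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "."
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                blocks = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            else:
                blocks = [(start, end)]
            yield Bed12Record(chrom, start, end, name, strand, blocks)


def write_bed12(records: Iterable[Bed12Record], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(r.to_line() + "\n")
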