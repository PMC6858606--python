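"""Contig assembly from DE k-mers, genomic alignment and catalog filtering.

Assembly is unitig-style: contigs are maximal non-branching paths in the
overlap graph linking k-mers whose (k-1)-suffix equals another's (k-1)-prefix,
so every contig remains a substring of a real transcript.  Mapped contigs are
categorized (contiguous / spliced / repeat / unmapped) and located relative to
the annotation (coding / OL / AS / Inter) with the precedence
coding > OL > AS > Inter; sense-coding contigs are excluded from the final
catalog, which keeps noncoding locations, length > 200 and adjusted p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import AnnotationIndex, Bed12Record, GenomicInterval
from .simulate import revcomp

_BASES = "ACGT"


@dataclass
class Alignment:
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]  # sorted genomic (start, end)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.blocks[0][0], self.blocks[-1][1], self.strand)


@dataclass
class Contig:
    contig_id: str
    sequence: str
    member_kmers: list[str]
    representative_kmer: str
    adjusted_p: float
    log2_fold_change: float
    alignments: list[Alignment] = field(default_factory=list)
    category: str = "unmapped"  # contiguous | spliced | repeat | unmapped
    location: str = "unassigned"  # Inter | OL | AS | coding | unassigned

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def primary(self) -> Alignment | None:
        return self.alignments[0] if self.alignments else None


def assemble_contigs(de_stats: pd.DataFrame, k: int) -> list[Contig]:
    """Assemble DE k-mers (index of `de_stats`, columns padj and log2FC)
    into maximal non-branching contigs.

    Every k-mer belongs to exactly one contig; the representative k-mer is
    the member with the smallest adjusted p (ties lexicographic) and the
    contig inherits its statistics.
    """
    kmers = list(de_stats.index)
    if any(len(km) != k for km in kmers):
        raise ValueError("all k-mers must have length k")
    kset = set(kmers)
    if len(kset) != len(kmers):
        raise ValueError("k-mers must be distinct")

    def successors(km: str) -> list[str]:
        suf = km[1:]
        return [suf + b for b in _BASES if suf + b in kset and suf + b != km]

    def predecessors(km: str) -> list[str]:
        pre = km[:-1]
        return [b + pre for b in _BASES if b + pre in kset and b + pre != km]

    visited: set[str] = set()
    paths: list[list[str]] = []

    def walk(start: str) -> list[str]:
        path = [start]
        visited.add(start)
        cur = start
        while True:
            succ = successors(cur)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if nxt in visited or len(predecessors(nxt)) != 1:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        return path

    # unitig starts: nodes not uniquely preceded
    for km in sorted(kmers):
        if km in visited:
            continue
        preds = predecessors(km)
        if len(preds) == 1 and len(successors(preds[0])) == 1:
            continue  # interior node, reached by a walk
        paths.append(walk(km))
    # leftover cycles: break at the lexicographically smallest member
    for km in sorted(kmers):
        if km not in visited:
            paths.append(walk(km))

    stats = de_stats[["padj", "log2FC"]]
    contigs: list[Contig] = []
    order = 0
    for path in paths:
        seq = path[0] + "".join(p[-1] for p in path[1:])
        rep = min(path, key=lambda km: (stats.at[km, "padj"], km))
        contigs.append(
            Contig(
                contig_id=f"ctg_{order:05d}",
                sequence=seq,
                member_kmers=path,
                representative_kmer=rep,
                adjusted_p=float(stats.at[rep, "padj"]),
                log2_fold_change=float(stats.at[rep, "log2FC"]),
            )
        )
        order += 1
    assert sum(len(c.member_kmers) for c in contigs) == len(kmers)
    return contigs


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _longest_hit(genome: str, s: str, from_start: bool, k: int) -> int:
    """Length of the longest prefix (or suffix) of `s`, >= k, found in genome
    (binary search on length; occurrence is monotone in length)."""
    lo, hi = k, len(s)
    probe = (lambda n: s[:n]) if from_start else (lambda n: s[-n:])
    if genome.find(probe(lo)) == -1:
        return 0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if genome.find(probe(mid)) != -1:
            lo = mid
        else:
            hi = mid - 1
    return lo


def align_contigs(
    contigs: Iterable[Contig],
    genome: dict[str, str],
    k: int = 31,
    max_intron: int = 300_000,
    external_bed12: Iterable[Bed12Record] | None = None,
) -> list[Contig]:
    """Attach genomic alignments to contigs.

    Internal mode finds all exact occurrences of the contig and its reverse
    complement; when none exist it attempts a two-block split (longest exact
    prefix + longest exact suffix, same chrom and strand, gap <= `max_intron`,
    both blocks >= k), reported as a spliced alignment.  External mode consumes
    BED12 records named by contig_id (e.g. from a real aligner).
    """
    contigs = list(contigs)
    if external_bed12 is not None:
        by_name: dict[str, list[Bed12Record]] = {}
        for rec in external_bed12:
            by_name.setdefault(rec.name, []).append(rec)
        for c in contigs:
            c.alignments = [
                Alignment(r.chrom, r.strand, sorted(r.blocks))
                for r in by_name.get(c.contig_id, [])
            ]
        return contigs

    for c in contigs:
        if len(c.sequence) < k:
            raise ValueError(f"{c.contig_id} shorter than k")
        hits: list[Alignment] = []
        for chrom, gseq in genome.items():
            for strand in "+-":
                s = c.sequence if strand == "+" else revcomp(c.sequence)
                for pos in _find_all(gseq, s):
                    hits.append(Alignment(chrom, strand, [(pos, pos + len(s))]))
        if not hits:
            hits = _spliced_hits(c, genome, k, max_intron)
        c.alignments = hits
    return contigs


def _spliced_hits(
    c: Contig, genome: dict[str, str], k: int, max_intron: int
) -> list[Alignment]:
    L = len(c.sequence)
    for chrom, gseq in genome.items():
        for strand in "+-":
            s = c.sequence if strand == "+" else revcomp(c.sequence)
            A = _longest_hit(gseq, s, True, k)
            B = _longest_hit(gseq, s, False, k)
            if A == 0 or B == 0 or A + B < L:
                continue
            # candidate split points: suffix-maximal then prefix-maximal
            for a in dict.fromkeys([L - B, min(A, L - k)]):
                if not (k <= a <= L - k) or a > A or L - a > B:
                    continue
                for p1 in _find_all(gseq, s[:a]):
                    for p2 in _find_all(gseq, s[a:]):
                        gap = p2 - (p1 + a)
                        if 0 < gap <= max_intron:
                            return [
                                Alignment(
                                    chrom, strand, [(p1, p1 + a), (p2, p2 + L - a)]
                                )
                            ]
    return []


def categorize_alignment(contig: Contig) -> str:
    """unmapped / repeat / spliced / contiguous; multiplicity beats splicing."""
    n = len(contig.alignments)
    if n == 0:
        cat = "unmapped"
    elif n > 1:
        cat = "repeat"
    elif len(contig.alignments[0].blocks) >= 2:
        cat = "spliced"
    else:
        cat = "contiguous"
    contig.category = cat
    return cat


def classify_location(contig: Contig, annotation: AnnotationIndex) -> str:
    """Genomic context of a uniquely mapped contig.

    Precedence: coding (same-strand protein-coding exon overlap) > OL
    (same-strand lncRNA gene overlap) > AS (opposite-strand gene overlap)
    > Inter.  Gene extents are used for OL/AS/Inter; exon-level overlap only
    for the coding exclusion.  Repeat/unmapped contigs stay unassigned.
    """
    if contig.category not in {"contiguous", "spliced"}:
        contig.location = "unassigned"
        return contig.location
    aln = contig.alignments[0]
    opp = "-" if aln.strand == "+" else "+"
    loc = "Inter"
    for s, e in aln.blocks:
        iv = GenomicInterval(aln.chrom, s, e, aln.strand)
        if annotation.exons_overlapping(iv, strand=aln.strand, biotype="protein_coding"):
            loc = "coding"
            break
        if any(
            g.biotype == "lncRNA"
            for g in annotation.genes_overlapping(iv, strand=aln.strand)
        ):
            loc = "OL"
        elif loc == "Inter" and annotation.genes_overlapping(iv, strand=opp):
            loc = "AS"
    contig.location = loc
    return loc


def filter_catalog(
    contigs: Iterable[Contig],
    min_length: int = 200,
    max_adjusted_p: float = 0.01,
    keep_locations: frozenset[str] | set[str] = frozenset({"Inter", "OL", "AS"}),
    keep_categories: frozenset[str] | set[str] = frozenset(
        {"contiguous", "spliced", "repeat", "unmapped"}
    ),
) -> list[Contig]:
    """The catalog filter: length strictly above `min_length`, adjusted p
    strictly below `max_adjusted_p`, noncoding location for mapped contigs,
    category whitelist for all."""
    out = []
    for c in contigs:
        if len(c.sequence) <= min_length or c.adjusted_p >= max_adjusted_p:
            continue
        if c.category not in keep_categories:
            continue
        if c.category in {"contiguous", "spliced"} and c.location not in keep_locations:
            continue
        out.append(c)
    return out


def window_dedup(contigs: Sequence[Contig], window: int = 5000) -> list[Contig]:
    """Within single-linkage clusters of alignment spans <= `window` apart on
    the same chromosome, keep only the lowest-adjusted-p contig (ties broken
    by contig_id).  Unmapped contigs pass through."""
    mapped = [c for c in contigs if c.alignments]
    unmapped = [c for c in contigs if not c.alignments]
    by_chrom: dict[str, list[Contig]] = {}
    for c in mapped:
        by_chrom.setdefault(c.primary.chrom, []).append(c)
    winners: list[Contig] = []
    for chrom, group in by_chrom.items():
        group.sort(key=lambda c: c.primary.span.start)
        cluster: list[Contig] = []
        cluster_end = -1
        for c in group:
            sp = c.primary.span
            if cluster and sp.start - cluster_end > window:
                winners.append(min(cluster, key=lambda x: (x.adjusted_p, x.contig_id)))
                cluster = []
                cluster_end = -1
            cluster.append(c)
            cluster_end = max(cluster_end, sp.end)
        if cluster:
            winners.append(min(cluster, key=lambda x: (x.adjusted_p, x.contig_id)))
    order = {c.contig_id: i for i, c in enumerate(contigs)}
    return sorted(winners + unmapped, key=lambda c: order[c.contig_id])


def overlap_fraction(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    fraction: float = 0.5,
    reciprocal: bool = False,
    stranded: bool = True,
) -> list[tuple[int, int]]:
    """Pairs (i, j) where b[j] covers >= `fraction` of a[i] (of both when
    reciprocal); strand-aware when both intervals carry a strand."""
    trees: dict[str, IntervalTree] = {}
    for j, y in enumerate(b):
        trees.setdefault(y.chrom, IntervalTree()).addi(y.start, y.end, j)
    pairs: list[tuple[int, int]] = []
    for i, x in enumerate(a):
        tree = trees.get(x.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(x.start, x.end), key=lambda h: h.data):
            y = b[hit.data]
            if stranded and x.strand != "." and y.strand != "." and x.strand != y.strand:
                continue
            ov = x.overlap_length(y)
            if ov / len(x) >= fraction and (not reciprocal or ov / len(y) >= fraction):
                pairs.append((i, hit.data))
    return pairs


def catalog_to_frame(contigs: Iterable[Contig]) -> pd.DataFrame:
    rows = []
    for c in contigs:
        aln = c.primary
        rows.append(
            {
                "contig_id": c.contig_id,
                "length": len(c.sequence),
                "representative_kmer": c.representative_kmer,
                "padj": c.adjusted_p,
                "log2FC": c.log2_fold_change,
                "category": c.category,
                "location": c.location,
                "chrom": aln.chrom if aln else "",
                "start": aln.span.start if aln else -1,
                "end": aln.span.end if aln else -1,
                "strand": aln.strand if aln else ".",
                "n_sites": len(c.alignments),
                "sequence": c.sequence,
            }
        )
    return pd.DataFrame(rows)


def catalog_to_bed12(contigs: Iterable[Contig]) -> list[Bed12Record]:
    out = []
    for c in contigs:
        aln = c.primary
        if aln is None:
            continue
        out.append(
            Bed12Record(
                aln.chrom,
                aln.blocks[0][0],
                aln.blocks[-1][1],
                c.contig_id,
                aln.strand,
                aln.blocks,
            )
        )
    return out
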