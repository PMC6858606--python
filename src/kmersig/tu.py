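"""Reference-based transcription-unit (TU) assembly from stranded coverage.

Uniquely mapped reads (mapping-quality filtered) are piled into per-strand
covered intervals, merged across samples, thresholded at a minimum read
support, and stitched into segments when separated by less than a maximum
gap.  Segments are classified against the annotation (antisense / intergenic
/ sense_overlap), quantified in RPKM, and promoted to Class 2 (expression
above the 0.2 quantile of mRNA expression in at least one condition) or
Class 1 (Class 2 plus at least one exon-exon junction and one spliced EST).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .intervals import AnnotationIndex, Bed12Record, GenomicInterval, merge_intervals


@dataclass
class TranscriptionUnit:
    tu_id: str
    interval: GenomicInterval
    supporting_read_count: int = 0
    tu_class: str = "below_threshold"  # class1 | class2 | below_threshold
    context: str = "intergenic"  # antisense | intergenic | sense_overlap
    rpkm: dict[str, float] = field(default_factory=dict)
    junction_count: int = 0
    spliced_est_count: int = 0

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Junction:
    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str

    def __post_init__(self) -> None:
        if not self.donor_end < self.acceptor_start:
            raise ValueError("donor_end must precede acceptor_start")


class JunctionSet:
    def __init__(self, support: Mapping[Junction, int] | None = None):
        self.support: dict[Junction, int] = dict(support or {})

    def add(self, j: Junction, n: int = 1) -> None:
        self.support[j] = self.support.get(j, 0) + n

    def __len__(self) -> int:
        return len(self.support)

    def within(self, iv: GenomicInterval) -> list[Junction]:
        return [
            j
            for j in self.support
            if j.chrom == iv.chrom
            and j.strand == iv.strand
            and iv.start <= j.donor_end
            and j.acceptor_start <= iv.end
        ]


def _read_strand(read: pysam.AlignedSegment, protocol: str) -> str:
    """Transcript strand implied by an aligned mate under the protocol."""
    aligned = "-" if read.is_reverse else "+"
    if protocol == "fr-firststrand":
        # dUTP: mate 1 is antisense to the transcript
        if read.is_read1 or not read.is_paired:
            return "-" if aligned == "+" else "+"
        return aligned
    if protocol == "fr-secondstrand":
        if read.is_read1 or not read.is_paired:
            return aligned
        return "-" if aligned == "+" else "+"
    return "."


def _iter_reads(path: str, min_mapq: int):
    """Yield reads from a coordinate-sorted SAM/BAM, checking sort order."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        last: dict[int, int] = {}
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            tid = read.reference_id
            if last.get(tid, -1) > read.reference_start:
                raise ValueError(
                    f"{path} is not coordinate-sorted; sort it first"
                )
            last[tid] = read.reference_start
            yield read


def _chrom_lengths(path: str) -> dict[str, int]:
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        return dict(zip(fh.references, fh.lengths))


def coverage_segments(
    sam_paths: Mapping[str, str],
    min_reads: int = 10,
    min_mapq: int = 50,
    protocol: str = "fr-firststrand",
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Maximal same-strand covered intervals, unioned over samples.

    An interval is retained when its supporting read count (reads overlapping
    it, same strand) reaches `min_reads` in at least one sample.
    """
    chrom_len: dict[str, int] = {}
    for p in sam_paths.values():
        chrom_len.update(_chrom_lengths(p))
    # union coverage masks and per-sample read interval lists
    cov: dict[tuple[str, str], np.ndarray] = {}
    reads_by_key: dict[tuple[str, str], dict[str, list[tuple[int, int]]]] = {}
    for sid, path in sam_paths.items():
        for read in _iter_reads(path, min_mapq):
            strand = _read_strand(read, protocol)
            key = (read.reference_name, strand)
            if key not in cov:
                cov[key] = np.zeros(chrom_len[read.reference_name] + 1, dtype=np.int32)
            arr = cov[key]
            span = (read.reference_start, read.reference_end)
            for s, e in read.get_blocks():
                arr[s] += 1
                arr[e] -= 1
            reads_by_key.setdefault(key, {}).setdefault(sid, []).append(span)

    out: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for key, arr in cov.items():
        depth = np.cumsum(arr[:-1])
        covered = depth > 0
        # runs of coverage
        edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
        intervals = list(zip(edges[::2], edges[1::2]))
        per_sample = reads_by_key.get(key, {})
        sorted_reads = {
            sid: (
                np.sort([s for s, _ in spans]),
                np.sort([e for _, e in spans]),
            )
            for sid, spans in per_sample.items()
        }
        kept = []
        for s, e in intervals:
            best = 0
            for starts, ends in sorted_reads.values():
                n = int(np.searchsorted(starts, e, side="left") - np.searchsorted(ends, s, side="right"))
                best = max(best, n)
            if best >= min_reads:
                kept.append((int(s), int(e)))
        if kept:
            out[key] = kept
    return out


def merge_segments(
    segments: Mapping[tuple[str, str], Sequence[tuple[int, int]]] | Sequence[tuple[int, int]],
    max_gap: int = 100,
) -> dict[tuple[str, str], list[tuple[int, int]]] | list[tuple[int, int]]:
    """Merge same-strand intervals separated by less than `max_gap` bp
    (gap <= max_gap - 1 merges; gap == max_gap does not).  Opposite strands
    are never merged."""
    if isinstance(segments, Mapping):
        return {k: merge_intervals(v, max_gap - 1) for k, v in segments.items()}
    return merge_intervals(segments, max_gap - 1)


def classify_tu(
    segments: Mapping[tuple[str, str], Sequence[tuple[int, int]]],
    annotation: AnnotationIndex,
    min_length: int = 200,
    keep_sense_overlap: bool = False,
) -> list[TranscriptionUnit]:
    """Turn merged segments into TUs with genomic context.

    Segments overlapping a same-strand annotated gene are sense_overlap and
    excluded from the lncRNA catalog (unless `keep_sense_overlap`); remaining
    segments are antisense (opposite-strand gene overlap) or intergenic, and
    retained only when strictly longer than `min_length`.
    """
    tus: list[TranscriptionUnit] = []
    n = 0
    for (chrom, strand), ivs in sorted(segments.items()):
        opp = "-" if strand == "+" else "+"
        for s, e in ivs:
            iv = GenomicInterval(chrom, s, e, strand)
            if annotation.genes_overlapping(iv, strand=strand):
                context = "sense_overlap"
            elif annotation.genes_overlapping(iv, strand=opp):
                context = "antisense"
            else:
                context = "intergenic"
            if context == "sense_overlap" and not keep_sense_overlap:
                continue
            if len(iv) <= min_length:
                continue
            tus.append(TranscriptionUnit(f"TU_{n:05d}", iv, context=context))
            n += 1
    return tus


def count_in_features(
    sam_paths: Mapping[str, str],
    features: Sequence[tuple[str, GenomicInterval]],
    paired: bool = True,
    strandedness: str = "reverse",
    multi_overlap: bool = True,
    min_mapq: int = 50,
) -> pd.DataFrame:
    """Count fragments (not mates) per feature per sample.

    With `strandedness="reverse"` (the -s 2 convention) the fragment strand is
    the opposite of mate 1's alignment strand; a fragment is assigned to every
    feature it overlaps on the consistent strand when `multi_overlap` (the -O
    semantics), and discarded as ambiguous otherwise.
    """
    if not features:
        raise ValueError("features must be non-empty")
    trees: dict[str, IntervalTree] = {}
    for idx, (fid, iv) in enumerate(features):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    counts = np.zeros((len(features), len(sam_paths)), dtype=np.int64)
    for j, (sid, path) in enumerate(sam_paths.items()):
        frags: dict[str, list[pysam.AlignedSegment]] = {}
        for read in _iter_reads(path, min_mapq):
            if paired and read.is_paired:
                frags.setdefault(read.query_name, []).append(read)
            else:
                frags.setdefault(read.query_name + "/s", []).append(read)
        for name, mates in frags.items():
            if paired and len(mates) not in (1, 2):
                warnings.warn(f"inconsistent pairing for {name}; using mates singly")
                groups = [[m] for m in mates]
            elif len(mates) == 2 and mates[0].reference_name != mates[1].reference_name:
                warnings.warn(f"mates of {name} on different references; using singly")
                groups = [[m] for m in mates]
            else:
                groups = [mates]
            for grp in groups:
                chrom = grp[0].reference_name
                start = min(m.reference_start for m in grp)
                end = max(m.reference_end for m in grp)
                mate1 = next((m for m in grp if m.is_read1 or not m.is_paired), grp[0])
                if strandedness == "reverse":
                    fstrand = "+" if mate1.is_reverse else "-"
                elif strandedness == "forward":
                    fstrand = "-" if mate1.is_reverse else "+"
                else:
                    fstrand = "."
                tree = trees.get(chrom)
                if tree is None:
                    continue
                hit_idx = []
                for hit in tree.overlap(start, end):
                    fiv = features[hit.data][1]
                    if fstrand != "." and fiv.strand != "." and fiv.strand != fstrand:
                        continue
                    hit_idx.append(hit.data)
                if not hit_idx:
                    continue
                if not multi_overlap and len(hit_idx) > 1:
                    continue
                for idx in hit_idx:
                    counts[idx, j] += 1
    return pd.DataFrame(
        counts, index=[fid for fid, _ in features], columns=list(sam_paths)
    )


def rpkm(count: float, feature_length_bp: float, library_total: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if feature_length_bp <= 0 or library_total <= 0:
        raise ValueError("length and library total must be positive")
    return count * 1e9 / (feature_length_bp * library_total)


def rpkm_matrix(
    counts: pd.DataFrame, lengths: Mapping[str, int], library_totals: Mapping[str, int]
) -> pd.DataFrame:
    L = np.array([lengths[f] for f in counts.index], dtype=float)
    T = np.array([library_totals[s] for s in counts.columns], dtype=float)
    return counts / L[:, None] / T[None, :] * 1e9


def extract_junctions(
    sam_paths: Mapping[str, str],
    protocol: str = "fr-firststrand",
    min_mapq: int = 50,
) -> JunctionSet:
    """Exon-exon junctions from gapped (N-operation) alignment records."""
    js = JunctionSet()
    for path in sam_paths.values():
        for read in _iter_reads(path, min_mapq):
            if not read.cigartuples:
                continue
            strand = _read_strand(read, protocol)
            pos = read.reference_start
            for op, ln in read.cigartuples:
                if op in (0, 2, 7, 8):  # M, D, =, X consume reference
                    pos += ln
                elif op == 3:  # N
                    js.add(Junction(read.reference_name, pos, pos + ln, strand))
                    pos += ln
    return js


def assign_classes(
    tus: Sequence[TranscriptionUnit],
    tu_rpkm: pd.DataFrame,
    mrna_rpkm: pd.DataFrame,
    conditions: Mapping[str, str],
    junctions: JunctionSet,
    ests: Sequence[Bed12Record],
    quantile: float = 0.2,
    condition_stat: str = "mean",
) -> list[TranscriptionUnit]:
    """Assign Class 1/2 labels.

    Class 2: TU condition-level RPKM (mean across the condition's samples by
    default) strictly above the `quantile` quantile of the mRNA condition-level
    RPKM distribution, in at least one condition.  Class 1: Class 2 and >= 1
    junction fully inside the TU on its strand and >= 1 spliced EST
    overlapping it.
    """
    if mrna_rpkm.empty:
        raise ValueError("empty mRNA reference set: expression threshold undefined")
    stat = {"mean": np.mean, "max": np.max}[condition_stat]
    groups: dict[str, list[str]] = {}
    for s, c in conditions.items():
        groups.setdefault(c, []).append(s)
    thresholds = {}
    for c, samples in groups.items():
        per_gene = mrna_rpkm[samples].apply(stat, axis=1)
        thresholds[c] = float(np.quantile(per_gene, quantile))
    est_trees: dict[str, IntervalTree] = {}
    for i, rec in enumerate(ests):
        if len(rec.blocks) < 2:
            continue  # only spliced ESTs count
        est_trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, i)
    for tu in tus:
        expr = tu_rpkm.loc[tu.tu_id]
        tu.rpkm = expr.to_dict()
        above = any(
            float(stat(expr[samples])) > thresholds[c] for c, samples in groups.items()
        )
        tu.junction_count = len(junctions.within(tu.interval))
        n_est = 0
        tree = est_trees.get(tu.interval.chrom)
        if tree is not None:
            for hit in tree.overlap(tu.interval.start, tu.interval.end):
                rec = ests[hit.data]
                if rec.strand in (".", tu.interval.strand):
                    n_est += 1
        tu.spliced_est_count = n_est
        if not above:
            tu.tu_class = "below_threshold"
        elif tu.junction_count >= 1 and tu.spliced_est_count >= 1:
            tu.tu_class = "class1"
        else:
            tu.tu_class = "class2"
    return list(tus)


def tus_to_bed6(tus: Iterable[TranscriptionUnit], path: str) -> None:
    with open(path, "w") as fh:
        for t in tus:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.tu_id}\t"
                f"{t.supporting_read_count}\t{iv.strand}\n"
            )


def tus_to_frame(tus: Iterable[TranscriptionUnit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tu_id": t.tu_id,
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "strand": t.interval.strand,
                "length": len(t),
                "context": t.context,
                "class": t.tu_class,
                "junctions": t.junction_count,
                "spliced_ests": t.spliced_est_count,
            }
            for t in tus
        ]
    )
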