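"""Contig quantification in independent libraries via probe k-mers.

A contig is quantified by its representative k-mer and, as a robustness
check, by the mean of k-mers sampled at regular positions along the contig
(restricted to k-mers unique in a reference transcript set).  Counts are
normalized to counts per million reads, and representative-vs-sampled
concordance is summarized per contig with a Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import iter_fastq
from .simulate import revcomp


def reference_kmer_occurrences(
    transcript_seqs: Iterable[str], k: int
) -> dict[str, int]:
    """Occurrence count of each k-mer across a reference transcript set
    (strand-specific, capped at 2 — beyond 'more than once' the exact count
    does not matter for uniqueness)."""
    occ: dict[str, int] = {}
    for seq in transcript_seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            c = occ.get(km, 0)
            if c < 2:
                occ[km] = c + 1
    return occ


def unique_contig_kmers(
    contig_seq: str,
    reference_occurrences: Mapping[str, int],
    k: int,
    max_occurrences: int = 1,
) -> list[str]:
    """Contig k-mers that are novel or unambiguous in the reference.

    Keeps k-mers occurring at most `max_occurrences` times in the reference
    (0 = novel, 1 = unambiguous), preserving contig 5'->3' order.
    """
    if len(contig_seq) < k:
        raise ValueError("contig shorter than k")
    out = []
    for i in range(len(contig_seq) - k + 1):
        km = contig_seq[i : i + k]
        if reference_occurrences.get(km, 0) <= max_occurrences:
            out.append(km)
    return out


def regular_sample(
    kmer_list: Sequence[str],
    n: int = 10,
    start_fraction: float = 0.10,
    end_fraction: float = 0.90,
    replicate_offsets: int = 4,
) -> list[list[str]]:
    """Deterministic regular sampling of `n` k-mers per replicate.

    Base positions are p_i = round(start*(L-1) + i*(end-start)*(L-1)/(n-1));
    replicate r shifts every index by r (clamped to the valid range) and
    collapses duplicates while preserving order.
    """
    L = len(kmer_list)
    if L == 0:
        raise ValueError("empty k-mer list")
    if L <= n:
        return [list(kmer_list) for _ in range(replicate_offsets)]
    span = (end_fraction - start_fraction) * (L - 1)
    base = [
        int(round(start_fraction * (L - 1) + i * span / (n - 1))) for i in range(n)
    ]
    reps = []
    for r in range(replicate_offsets):
        idx = [min(max(p + r, 0), L - 1) for p in base]
        seen: set[int] = set()
        picks = []
        for i in idx:
            if i not in seen:
                seen.add(i)
                picks.append(kmer_list[i])
        reps.append(picks)
    return reps


@dataclass
class ProbeKmerSet:
    contig_id: str
    representative_kmer: str
    unique_kmers: list[str]
    sampled_sets: list[list[str]] = field(default_factory=list)

    @classmethod
    def build(
        cls,
        contig_id: str,
        contig_seq: str,
        representative_kmer: str,
        reference_occurrences: Mapping[str, int],
        k: int,
        n_sample: int = 10,
        replicate_offsets: int = 4,
    ) -> "ProbeKmerSet":
        uniq = unique_contig_kmers(contig_seq, reference_occurrences, k)
        sampled = regular_sample(uniq, n=n_sample, replicate_offsets=replicate_offsets) if uniq else []
        return cls(contig_id, representative_kmer, uniq, sampled)

    def all_query_kmers(self) -> set[str]:
        out = {self.representative_kmer}
        for s in self.sampled_sets:
            out.update(s)
        return out

    def to_query_frame(self) -> pd.DataFrame:
        rows = [
            {"contig_id": self.contig_id, "kmer": self.representative_kmer, "role": "representative"}
        ]
        for r, picks in enumerate(self.sampled_sets):
            for km in picks:
                rows.append({"contig_id": self.contig_id, "kmer": km, "role": f"sampled_r{r}"})
        return pd.DataFrame(rows)


def stream_count(
    reads: Iterable[str] | str,
    query_kmers: Iterable[str],
    stranded: bool = False,
) -> tuple[dict[str, int], int]:
    """Single-pass occurrence counts of query k-mers over a read stream.

    `reads` is an iterable of sequences or a FASTQ path.  For unstranded
    libraries a k-mer and its reverse complement both credit the query; for
    stranded libraries only the sense form counts.  Returns (counts per query
    k-mer, total read count).
    """
    queries = list(dict.fromkeys(query_kmers))
    if not queries:
        raise ValueError("query set must be non-empty")
    ks = {len(q) for q in queries}
    if len(ks) != 1:
        raise ValueError("query k-mers must share a single length")
    k = ks.pop()
    lookup: dict[str, str] = {}
    for q in queries:
        lookup[q] = q
        if not stranded:
            lookup.setdefault(revcomp(q), q)
    counts = {q: 0 for q in queries}
    if isinstance(reads, str):
        reads = iter_fastq(reads)
    total = 0
    for seq in reads:
        total += 1
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            hit = lookup.get(seq[i : i + k])
            if hit is not None:
                counts[hit] += 1
    return counts, total


def normalize_counts(raw: float | np.ndarray, library_total_reads: int) -> float | np.ndarray:
    """Counts per million reads."""
    if library_total_reads <= 0:
        raise ValueError("library total must be positive")
    return np.asarray(raw, dtype=float) * 1e6 / library_total_reads


def concordance(
    representative: pd.DataFrame, sampled_mean: pd.DataFrame
) -> pd.Series:
    """Per-contig Pearson r between representative-k-mer counts and mean
    sampled-k-mer counts across libraries (NaN when a vector is constant)."""
    if representative.shape != sampled_mean.shape:
        raise ValueError("matrices must share shape (contigs x libraries)")
    if representative.shape[1] < 3:
        raise ValueError("need >= 3 libraries")
    out = {}
    for cid in representative.index:
        x = representative.loc[cid].to_numpy(dtype=float)
        y = sampled_mean.loc[cid].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[cid] = np.nan
        else:
            out[cid] = float(stats.pearsonr(x, y)[0])
    return pd.Series(out, name="pearson_r")


def quantify_libraries(
    probe_sets: Sequence[ProbeKmerSet],
    libraries: Mapping[str, Iterable[str] | str],
    stranded: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Count representative and sampled k-mers across libraries.

    Returns (representative CPM, mean-sampled CPM averaged over the sampled
    replicates, library totals)."""
    queries: set[str] = set()
    for ps in probe_sets:
        queries.update(ps.all_query_kmers())
    rep = pd.DataFrame(index=[p.contig_id for p in probe_sets], columns=list(libraries), dtype=float)
    samp = rep.copy()
    totals = pd.Series(0, index=list(libraries), dtype=int)
    for lib, reads in libraries.items():
        counts, total = stream_count(reads, queries, stranded=stranded)
        totals[lib] = total
        scale = 1e6 / total if total > 0 else 0.0
        for ps in probe_sets:
            rep.loc[ps.contig_id, lib] = counts[ps.representative_kmer] * scale
            if ps.sampled_sets:
                rep_means = [
                    np.mean([counts[km] for km in picks]) for picks in ps.sampled_sets
                ]
                samp.loc[ps.contig_id, lib] = float(np.mean(rep_means)) * scale
            else:
                samp.loc[ps.contig_id, lib] = np.nan
    return rep, samp, totals
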