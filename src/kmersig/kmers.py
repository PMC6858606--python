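"""Streaming k-mer counting, annotation masking and multi-sample joining.

Counting is strand-aware: under the fr-firststrand protocol mate 1 is
reverse-complemented and mate 2 taken as-is before decomposition, so every
counted k-mer is in the transcript's sense orientation.  Masking removes
k-mers exactly matching an annotated transcript set, same strand only —
antisense transcription would be annihilated by strand-agnostic masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .simulate import revcomp

_VALID = frozenset("ACGT")


@dataclass
class KmerCountTable:
    k: int
    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class KmerSet:
    k: int
    members: set[str] = field(default_factory=set)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class JoinedKmerMatrix:
    k: int
    sample_ids: list[str]
    rows: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        if not self.rows:
            return pd.DataFrame(columns=self.sample_ids)
        df = pd.DataFrame.from_dict(self.rows, orient="index", columns=self.sample_ids)
        return df.astype(np.int64)

    def to_tsv(self, path: str) -> None:
        df = self.to_frame()
        df.index.name = "kmer"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str) -> "JoinedKmerMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        k = len(df.index[0]) if len(df) else 0
        rows = {km: df.loc[km].to_numpy(dtype=np.int64) for km in df.index}
        return cls(k, list(df.columns), rows)


def iter_fastq(path: str) -> Iterator[str]:
    """Yield read sequences from a (optionally gzipped) FASTQ file."""
    import gzip

    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as fh:
        try:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                yield seq
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


def _add_kmers(counts: dict[str, int], seq: str, k: int) -> None:
    seq = seq.upper()
    get = counts.get
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if _VALID.issuperset(km):
            counts[km] = get(km, 0) + 1


def count_kmers(
    read_pairs: Iterable[tuple[str, str | None]],
    k: int,
    protocol: str = "fr-firststrand",
    sample_id: str = "sample",
) -> KmerCountTable:
    """Count transcript-oriented k-mers from a stream of read pairs.

    `read_pairs` yields (mate1, mate2) sequences; mate2 may be None for
    single-end input.  Windows containing non-ACGT symbols are skipped.
    """
    if not (11 <= k <= 63):
        raise ValueError("k must be in [11, 63]")
    if protocol not in {"fr-firststrand", "fr-secondstrand", "unstranded"}:
        raise ValueError(f"unknown protocol {protocol!r}")
    counts: dict[str, int] = {}
    for r1, r2 in read_pairs:
        if protocol == "fr-firststrand":
            if r1:
                _add_kmers(counts, revcomp(r1), k)
            if r2:
                _add_kmers(counts, r2, k)
        elif protocol == "fr-secondstrand":
            if r1:
                _add_kmers(counts, r1, k)
            if r2:
                _add_kmers(counts, revcomp(r2), k)
        else:
            if r1:
                _add_kmers(counts, r1, k)
            if r2:
                _add_kmers(counts, r2, k)
    return KmerCountTable(k, sample_id, counts)


def count_kmers_fastq(
    path1: str,
    path2: str | None,
    k: int,
    protocol: str = "fr-firststrand",
    sample_id: str | None = None,
) -> KmerCountTable:
    def pairs():
        it1 = iter_fastq(path1)
        it2 = iter_fastq(path2) if path2 else iter(lambda: None, object())
        if path2:
            yield from zip(it1, it2)
        else:
            for s in it1:
                yield s, None

    return count_kmers(pairs(), k, protocol, sample_id or str(path1))


def build_mask(transcript_seqs: Iterable[str], k: int) -> KmerSet:
    """All k-mers of the given sense transcript sequences (same strand only)."""
    members: set[str] = set()
    for seq in transcript_seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if _VALID.issuperset(km):
                members.add(km)
    if not members:
        import warnings

        warnings.warn("empty transcript set: mask is empty", stacklevel=2)
    return KmerSet(k, members)


def build_mask_fasta(path: str, k: int) -> KmerSet:
    from Bio import SeqIO

    return build_mask((str(rec.seq) for rec in SeqIO.parse(path, "fasta")), k)


def apply_mask(table: KmerCountTable, mask: KmerSet) -> KmerCountTable:
    if table.k != mask.k:
        raise ValueError(f"k mismatch: table k={table.k}, mask k={mask.k}")
    kept = {km: c for km, c in table.counts.items() if km not in mask.members}
    return KmerCountTable(table.k, table.sample_id, kept)


def join_samples(
    tables: Sequence[KmerCountTable],
    min_recurrence: int = 6,
    min_recurrence_abundance: int = 5,
) -> JoinedKmerMatrix:
    """Join per-sample counts, keeping k-mers whose count reaches
    `min_recurrence_abundance` in at least `min_recurrence` samples
    (evaluated jointly over all samples, both conditions)."""
    if not tables:
        return JoinedKmerMatrix(0, [], {})
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise ValueError("all tables must share k")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in joined tables")
    if min_recurrence > len(tables):
        raise ValueError("min_recurrence exceeds the number of samples")
    recurrence: dict[str, int] = {}
    for t in tables:
        for km, c in t.counts.items():
            if c >= min_recurrence_abundance:
                recurrence[km] = recurrence.get(km, 0) + 1
    keep = [km for km, r in recurrence.items() if r >= min_recurrence]
    rows: dict[str, np.ndarray] = {}
    for km in keep:
        rows[km] = np.array([t.counts.get(km, 0) for t in tables], dtype=np.int64)
    return JoinedKmerMatrix(k, ids, rows)
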