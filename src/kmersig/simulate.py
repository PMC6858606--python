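"""Synthetic two-condition stranded RNA-seq cohorts with planted novel RNAs.

The generator emulates the study design the pipeline targets: a small genome
carrying annotated protein-coding and lncRNA gene models, a set of planted
unannotated transcription events (intergenic lncRNAs, antisense lncRNAs, exon
extensions, novel splice variants) up-regulated in the second condition, and
stranded paired-end read sets with negative-binomial count variation.
Alignments are emitted directly from the known fragment coordinates, so the
downstream reference-based stages can be exercised without an aligner.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .intervals import Bed12Record, GeneRecord, GenomicInterval

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    n_per_group follows the discovery design (8 normal vs 16 tumor).  The
    stranded protocol defaults to fr-firststrand, the orientation produced by
    dUTP-based stranded library preparations: mate 2 reads the transcript
    sense strand and mate 1 its reverse complement.
    """

    genome_length: int = 1_000_000
    n_genes: int = 200
    n_events: int = 20
    n_per_group: tuple[int, int] = (8, 16)
    read_length: int = 100
    fragment_mean: int = 250
    fragment_sd: int = 40
    substitution_rate: float = 0.005
    nb_dispersion: float = 0.1
    protocol: str = "fr-firststrand"
    seed: int = 0
    # expression levels (expected fragments per transcript per sample)
    gene_mean: float = 10.0
    event_baseline_mean: float = 6.0
    effect_floor: float = 6.0  # minimum fold change of planted events
    effect_ceiling: float = 12.0
    est_fraction: float = 0.6  # fraction of spliced transcripts with an EST
    min_intergenic: int = 150

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_genes < 0 or self.n_events < 0:
            raise ValueError("counts must be non-negative, genome positive")
        if min(self.n_per_group) < 1:
            raise ValueError("both groups need at least one sample")
        if not (0.0 <= self.substitution_rate <= 0.1):
            raise ValueError("substitution_rate must be in [0, 0.1]")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.fragment_mean < self.read_length:
            raise ValueError("fragment_mean must be >= read_length")
        if self.protocol not in {"fr-firststrand", "fr-secondstrand", "unstranded"}:
            raise ValueError(f"unknown protocol {self.protocol!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "n_per_group" in raw:
            raw["n_per_group"] = tuple(raw["n_per_group"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["n_per_group"] = list(d["n_per_group"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


@dataclass
class Reference:
    genome: dict[str, str]
    genes: list[GeneRecord]
    transcripts: dict[str, str]  # transcript id -> sense sequence
    transcript_exons: dict[str, tuple[str, str, list[tuple[int, int]]]]
    ests: list[Bed12Record]

    def write_genome_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_transcript_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for tid, seq in self.transcripts.items():
                fh.write(f">{tid}\n{seq}\n")


@dataclass(frozen=True)
class PlantedEvent:
    event_id: str
    type: str  # intergenic_lnc | antisense_lnc | exon_extension | splice_variant
    interval: GenomicInterval
    strand: str
    log2_effect: float
    baseline_mean: float
    exons: tuple[tuple[int, int], ...]


@dataclass
class TruthManifest:
    events: list[PlantedEvent]

    def validate(self, genes: Sequence[GeneRecord], genome_length: int) -> None:
        """Independent brute-force check of every event's class definition."""
        for ev in self.events:
            iv = ev.interval
            if not (0 <= iv.start < iv.end <= genome_length):
                raise AssertionError(f"{ev.event_id} outside genome")
            same = [g for g in genes if g.strand == iv.strand and g.interval.overlaps(iv)]
            anti = [g for g in genes if g.strand != iv.strand and g.interval.overlaps(iv)]
            if ev.type in {"intergenic_lnc", "splice_variant"}:
                if same or anti:
                    raise AssertionError(f"{ev.event_id} overlaps a gene")
            elif ev.type == "antisense_lnc":
                if same:
                    raise AssertionError(f"{ev.event_id} overlaps same-strand gene")
                if not anti:
                    raise AssertionError(f"{ev.event_id} has no antisense partner")

    def to_tsv(self, path: str) -> None:
        rows = []
        for ev in self.events:
            rows.append(
                {
                    "event_id": ev.event_id,
                    "type": ev.type,
                    "chrom": ev.interval.chrom,
                    "start": ev.interval.start,
                    "end": ev.interval.end,
                    "strand": ev.strand,
                    "log2_effect": ev.log2_effect,
                    "baseline_mean": ev.baseline_mean,
                    "exons": ";".join(f"{s}-{e}" for s, e in ev.exons),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _draw_gene_structure(
    rng: np.random.Generator, biotype: str
) -> list[tuple[int, int]]:
    """Relative exon coordinates (start at 0) for one gene model."""
    n_exons = int(rng.integers(1, 4)) if biotype == "lncRNA" else int(rng.integers(2, 5))
    exons = []
    pos = 0
    for i in range(n_exons):
        elen = int(rng.integers(150, 400))
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_exons - 1:
            pos += int(rng.integers(100, 800))
    return exons


def make_reference(cfg: SimConfig) -> Reference:
    """Generate genome, multi-exon gene models, transcripts and spliced ESTs."""
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    genome = _random_seq(rng, cfg.genome_length)

    structures = []
    for i in range(cfg.n_genes):
        biotype = "protein_coding" if rng.random() < 0.7 else "lncRNA"
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _draw_gene_structure(rng, biotype)
        structures.append((biotype, strand, exons))
    spans = [ex[-1][1] for _, _, ex in structures] if structures else []
    needed = sum(spans) + (cfg.n_genes + 1) * cfg.min_intergenic
    if needed > cfg.genome_length:
        raise ValueError(
            f"genome of {cfg.genome_length} bp too short for {cfg.n_genes} genes "
            f"(need >= {needed} bp)"
        )
    # distribute the slack over the n_genes+1 intergenic gaps
    slack = cfg.genome_length - needed
    if cfg.n_genes:
        cuts = np.sort(rng.integers(0, slack + 1, cfg.n_genes))
        gaps = np.diff(np.concatenate([[0], cuts, [slack]])) + cfg.min_intergenic
    else:
        gaps = np.array([slack + cfg.min_intergenic])

    genes: list[GeneRecord] = []
    transcripts: dict[str, str] = {}
    transcript_exons: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    ests: list[Bed12Record] = []
    pos = 0
    for i, (biotype, strand, rel_exons) in enumerate(structures):
        pos += int(gaps[i])
        exons = [(pos + s, pos + e) for s, e in rel_exons]
        gid = f"gene_{i:04d}"
        g = GeneRecord(gid, chrom, exons[0][0], exons[-1][1], strand, biotype, exons)
        genes.append(g)
        tid = f"tx_{i:04d}"
        transcripts[tid] = spliced_sequence(genome, exons, strand)
        transcript_exons[tid] = (chrom, strand, exons)
        if len(exons) > 1 and rng.random() < cfg.est_fraction:
            ests.append(
                Bed12Record(chrom, exons[0][0], exons[-1][1], f"est_{i:04d}", strand, exons)
            )
        pos += rel_exons[-1][1]
    return Reference({chrom: genome}, genes, transcripts, transcript_exons, ests)


def spliced_sequence(genome: str, exons: list[tuple[int, int]], strand: str) -> str:
    seq = "".join(genome[s:e] for s, e in exons)
    return seq if strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# event planting


def _free_gaps(
    genes: Sequence[GeneRecord], genome_length: int, clearance: int
) -> list[tuple[int, int]]:
    """Intergenic gaps shrunk by `clearance` on both sides."""
    edges = sorted((g.start, g.end) for g in genes)
    gaps = []
    prev = 0
    for s, e in edges:
        if s - prev >= 2 * clearance:
            gaps.append((prev + clearance, s - clearance))
        prev = max(prev, e)
    if genome_length - prev >= 2 * clearance:
        gaps.append((prev + clearance, genome_length - clearance))
    return gaps


def plant_events(
    reference: Reference,
    cfg: SimConfig,
    type_mix: dict[str, int] | None = None,
) -> TruthManifest:
    """Plant unannotated transcription events with known effect sizes.

    Effect sizes are drawn uniformly on the log2 scale between the configured
    fold-change floor and ceiling, so every event is expressed at least
    `effect_floor` times more in the second condition.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if type_mix is None:
        n_as = cfg.n_events // 2
        type_mix = {"intergenic_lnc": cfg.n_events - n_as, "antisense_lnc": n_as}
    if sum(type_mix.values()) != cfg.n_events:
        raise ValueError("type_mix must sum to n_events")
    chrom = next(iter(reference.genome))
    genome_length = len(reference.genome[chrom])
    genes = reference.genes
    gaps = _free_gaps(genes, genome_length, clearance=100)
    rng.shuffle(gaps)
    events: list[PlantedEvent] = []
    idx = 0

    def draw_effect() -> float:
        lo, hi = np.log2(cfg.effect_floor), np.log2(cfg.effect_ceiling)
        return float(rng.uniform(lo, hi))

    def take_gap(need: int) -> tuple[int, int]:
        for gi, (s, e) in enumerate(gaps):
            if e - s >= need:
                start = int(rng.integers(s, e - need + 1))
                # split the remaining gap so later events stay disjoint
                del gaps[gi]
                if start - s >= 1:
                    gaps.append((s, start))
                if e - (start + need) >= 1:
                    gaps.append((start + need, e))
                return start, start + need
        raise ValueError("no free intergenic space left to place an event")

    for etype, n in type_mix.items():
        for _ in range(n):
            eid = f"event_{idx:03d}"
            idx += 1
            if etype == "intergenic_lnc":
                length = int(rng.integers(450, 800))
                s, e = take_gap(length)
                strand = "+" if rng.random() < 0.5 else "-"
                exons = ((s, e),)
                iv = GenomicInterval(chrom, s, e, strand)
            elif etype == "antisense_lnc":
                hosts = [g for g in genes if (g.end - g.start) >= 500]
                if not hosts:
                    raise ValueError("no gene long enough to host an antisense event")
                placed = False
                for _attempt in range(200):
                    g = hosts[int(rng.integers(0, len(hosts)))]
                    length = min(600, g.end - g.start - 20)
                    s = int(rng.integers(g.start + 10, g.end - length - 9))
                    e = s + length
                    strand = "-" if g.strand == "+" else "+"
                    probe = GenomicInterval(chrom, s, e, strand)
                    # reject placements touching a same-strand neighbour
                    if any(
                        h.strand == strand and h.interval.overlaps(probe) for h in genes
                    ):
                        continue
                    placed = True
                    break
                if not placed:
                    raise ValueError("could not place antisense event")
                exons = ((s, e),)
                iv = GenomicInterval(chrom, s, e, strand)
            elif etype == "exon_extension":
                hosts = [g for g in genes]
                rng.shuffle(hosts)
                placed = False
                for g in hosts:
                    ext_len = int(rng.integers(300, 600))
                    if g.strand == "+":
                        s, e = g.end, g.end + ext_len
                    else:
                        s, e = g.start - ext_len, g.start
                    if s < 0 or e > genome_length:
                        continue
                    probe = GenomicInterval(chrom, s, e, g.strand)
                    if any(h is not g and h.interval.overlaps(probe) for h in genes):
                        continue
                    last_exon = g.exons[-1] if g.strand == "+" else g.exons[0]
                    exons = tuple(sorted([last_exon, (s, e)]))
                    # merge if contiguous
                    if exons[0][1] >= exons[1][0]:
                        exons = ((exons[0][0], exons[1][1]),)
                    iv = GenomicInterval(chrom, s, e, g.strand)
                    strand = g.strand
                    placed = True
                    break
                if not placed:
                    raise ValueError("could not place exon extension event")
            elif etype == "splice_variant":
                e1 = int(rng.integers(250, 400))
                e2 = int(rng.integers(250, 400))
                intron = int(rng.integers(200, 1500))
                s, e = take_gap(e1 + intron + e2)
                strand = "+" if rng.random() < 0.5 else "-"
                exons = ((s, s + e1), (e - e2, e))
                iv = GenomicInterval(chrom, s, e, strand)
            else:
                raise ValueError(f"unknown event type {etype!r}")
            events.append(
                PlantedEvent(
                    eid, etype, iv, strand, draw_effect(), cfg.event_baseline_mean, exons
                )
            )
    manifest = TruthManifest(events)
    manifest.validate(genes, genome_length)
    return manifest


def event_transcripts(
    reference: Reference, truth: TruthManifest
) -> dict[str, tuple[str, str, list[tuple[int, int]], str]]:
    """Sense sequences and exon structures of the planted event transcripts."""
    chrom = next(iter(reference.genome))
    genome = reference.genome[chrom]
    out = {}
    for ev in truth.events:
        seq = spliced_sequence(genome, list(ev.exons), ev.strand)
        out[ev.event_id] = (chrom, ev.strand, list(ev.exons), seq)
    return out


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str
    # alignment of each mate: (ref_start, blocks, aligned_strand)
    chrom: str
    mate1_blocks: list[tuple[int, int]]
    mate2_blocks: list[tuple[int, int]]
    mate1_strand: str
    mate2_strand: str


@dataclass
class SimulatedCohort:
    sample_ids: list[str]
    conditions: dict[str, str]  # sample -> "A" | "B"
    reads: dict[str, list[ReadPair]]
    true_counts: pd.DataFrame  # transcripts x samples (fragments)
    chrom_lengths: dict[str, int]

    def write_fastq(self, outdir: str, gz: bool = False) -> dict[str, tuple[str, str]]:
        import os

        paths = {}
        for sid in self.sample_ids:
            suffix = ".fastq.gz" if gz else ".fastq"
            p1 = os.path.join(outdir, f"{sid}_1{suffix}")
            p2 = os.path.join(outdir, f"{sid}_2{suffix}")
            op = gzip.open if gz else open
            with op(p1, "wt") as f1, op(p2, "wt") as f2:
                for rp in self.reads[sid]:
                    q1 = "I" * len(rp.seq1)
                    q2 = "I" * len(rp.seq2)
                    f1.write(f"@{rp.name}/1\n{rp.seq1}\n+\n{q1}\n")
                    f2.write(f"@{rp.name}/2\n{rp.seq2}\n+\n{q2}\n")
            paths[sid] = (p1, p2)
        return paths

    def write_sam(self, outdir: str) -> dict[str, str]:
        """Coordinate-sorted SAM per sample, emitted from known coordinates."""
        import os

        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": n} for c, n in self.chrom_lengths.items()],
        }
        paths = {}
        for sid in self.sample_ids:
            path = os.path.join(outdir, f"{sid}.sam")
            segments = []
            with pysam.AlignmentFile(path, "wh", header=header) as fh:
                for rp in self.reads[sid]:
                    segments.extend(_pair_to_segments(rp, fh.header))
                segments.sort(key=lambda a: (a.reference_id, a.reference_start))
                for seg in segments:
                    fh.write(seg)
            paths[sid] = path
        return paths


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            cig.append((3, gap))  # N
        cig.append((0, e - s))  # M
    return cig


def _pair_to_segments(rp: ReadPair, header) -> list[pysam.AlignedSegment]:
    out = []
    specs = [
        (rp.seq1, rp.mate1_blocks, rp.mate1_strand, True),
        (rp.seq2, rp.mate2_blocks, rp.mate2_strand, False),
    ]
    for (seq, blocks, strand, is_read1), (oseq, oblocks, ostrand, _) in zip(
        specs, specs[::-1]
    ):
        a = pysam.AlignedSegment(header)
        a.query_name = rp.name
        a.reference_id = header.get_tid(rp.chrom)
        a.reference_start = blocks[0][0]
        a.cigartuples = _blocks_to_cigar(blocks)
        a.query_sequence = seq if strand == "+" else revcomp(seq)
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        a.mapping_quality = 60
        flag = 1 | 2  # paired, proper pair
        flag |= 64 if is_read1 else 128
        if strand == "-":
            flag |= 16
        if ostrand == "-":
            flag |= 32
        a.flag = flag
        a.next_reference_id = a.reference_id
        a.next_reference_start = oblocks[0][0]
        lo = min(blocks[0][0], oblocks[0][0])
        hi = max(blocks[-1][1], oblocks[-1][1])
        a.template_length = (hi - lo) if blocks[0][0] <= oblocks[0][0] else -(hi - lo)
        out.append(a)
    return out


def _map_interval(
    exons: list[tuple[int, int]], strand: str, a: int, b: int
) -> list[tuple[int, int]]:
    """Map transcript-coordinate interval [a, b) onto genomic blocks."""
    lens = [e - s for s, e in exons]
    total = sum(lens)
    if strand == "-":
        a, b = total - b, total - a
    blocks = []
    off = 0
    for (s, e), ln in zip(exons, lens):
        lo = max(a, off)
        hi = min(b, off + ln)
        if lo < hi:
            blocks.append((s + (lo - off), s + (hi - off)))
        off += ln
    return blocks


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    nmut = rng.binomial(n, rate)
    if nmut == 0:
        return seq
    pos = rng.choice(n, size=nmut, replace=False)
    chars = list(seq)
    bases = "ACGT"
    for p in pos:
        alt = bases[int(rng.integers(0, 4))]
        while alt == chars[p]:
            alt = bases[int(rng.integers(0, 4))]
        chars[p] = alt
    return "".join(chars)


def simulate_reads(
    truth: TruthManifest, reference: Reference, cfg: SimConfig
) -> SimulatedCohort:
    """Simulate stranded paired-end reads for a two-condition cohort.

    Per-transcript fragment counts are negative-binomial (gamma-Poisson)
    around the group mean; planted event transcripts are up-shifted in the
    second condition by 2**log2_effect.  Reads follow the configured stranded
    protocol and carry substitution errors at the configured rate.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    chrom = next(iter(reference.genome))
    nA, nB = cfg.n_per_group
    sample_ids = [f"A{i+1:02d}" for i in range(nA)] + [f"B{i+1:02d}" for i in range(nB)]
    conditions = {s: ("A" if s.startswith("A") else "B") for s in sample_ids}

    # transcript universe: background genes + planted events
    tx: dict[str, tuple[str, str, list[tuple[int, int]], str]] = {}
    for tid, seq in reference.transcripts.items():
        c, st, ex = reference.transcript_exons[tid]
        tx[tid] = (c, st, ex, seq)
    tx.update(event_transcripts(reference, truth))

    # group means
    base_mean: dict[str, float] = {}
    effect: dict[str, float] = {}
    for tid in reference.transcripts:
        base_mean[tid] = float(rng.lognormal(np.log(cfg.gene_mean), 0.6))
        effect[tid] = 1.0
    for ev in truth.events:
        base_mean[ev.event_id] = ev.baseline_mean
        effect[ev.event_id] = float(2.0 ** ev.log2_effect)

    tids = list(tx)
    counts = np.zeros((len(tids), len(sample_ids)), dtype=int)
    reads: dict[str, list[ReadPair]] = {s: [] for s in sample_ids}
    for j, sid in enumerate(sample_ids):
        grp = conditions[sid]
        for i, tid in enumerate(tids):
            c, st, exons, seq = tx[tid]
            mu = base_mean[tid] * (effect[tid] if grp == "B" else 1.0)
            if cfg.nb_dispersion > 1e-12:
                lam = rng.gamma(1.0 / cfg.nb_dispersion, mu * cfg.nb_dispersion)
            else:
                lam = mu
            n_frag = int(rng.poisson(lam))
            L = len(seq)
            if L < cfg.read_length:
                n_frag = 0
            counts[i, j] = n_frag
            for f in range(n_frag):
                flen = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
                flen = int(np.clip(flen, cfg.read_length, L))
                start = int(rng.integers(0, L - flen + 1))
                frag = seq[start : start + flen]
                sense = frag[: cfg.read_length]
                anti = revcomp(frag[-cfg.read_length :])
                sense_blocks = _map_interval(exons, st, start, start + cfg.read_length)
                anti_blocks = _map_interval(exons, st, start + flen - cfg.read_length, start + flen)
                if cfg.protocol == "fr-firststrand":
                    seq1, seq2 = anti, sense
                    b1, b2 = anti_blocks, sense_blocks
                    s1, s2 = ("-", "+") if st == "+" else ("+", "-")
                elif cfg.protocol == "fr-secondstrand":
                    seq1, seq2 = sense, anti
                    b1, b2 = sense_blocks, anti_blocks
                    s1, s2 = ("+", "-") if st == "+" else ("-", "+")
                else:  # unstranded: random fragment orientation
                    if rng.random() < 0.5:
                        seq1, seq2 = anti, sense
                        b1, b2 = anti_blocks, sense_blocks
                        s1, s2 = ("-", "+") if st == "+" else ("+", "-")
                    else:
                        seq1, seq2 = sense, anti
                        b1, b2 = sense_blocks, anti_blocks
                        s1, s2 = ("+", "-") if st == "+" else ("-", "+")
                name = f"{sid}:{tid}:{f}"
                reads[sid].append(
                    ReadPair(
                        name,
                        _mutate(rng, seq1, cfg.substitution_rate),
                        _mutate(rng, seq2, cfg.substitution_rate),
                        c,
                        b1,
                        b2,
                        s1,
                        s2,
                    )
                )
    true_counts = pd.DataFrame(counts, index=tids, columns=sample_ids)
    return SimulatedCohort(
        sample_ids,
        conditions,
        reads,
        true_counts,
        {chrom: len(reference.genome[chrom])},
    )


# ---------------------------------------------------------------------------
# probe tables (NanoString-style)


def make_probe_table(
    n_targets: int = 23,
    n_per_class: tuple[int, int] = (9, 135),
    effects: Sequence[float] | float = 6.0,
    n_housekeeping: int = 6,
    n_pos_controls: int = 6,
    n_neg_controls: int = 8,
    benchmark_effect: float | None = 3.0,
    target_mean: float = 200.0,
    noise_sd: float = 0.35,
    seed: int = 0,
):
    """Synthetic probe count table with control rows and clinical labels.

    Emulates a multiplex digital-counting assay: positive-control ladder and
    negative-control background per lane, housekeeping probes with no class
    effect, and target probes whose tumor/normal fold changes are given by
    `effects`.  Measurement noise is log-normal; per-lane scale factors are
    applied to every row so control-based normalization has something to
    remove.  Returns a :class:`kmersig.probes.ProbeTable`.
    """
    from .probes import ProbeTable

    rng = np.random.default_rng(seed)
    n_norm, n_tum = n_per_class
    if min(n_norm, n_tum) < 1:
        raise ValueError("both classes need at least one sample")
    n_samples = n_norm + n_tum
    if np.isscalar(effects):
        effects = [float(effects)] * n_targets
    effects = list(effects)
    if len(effects) != n_targets:
        raise ValueError("effects length must equal n_targets")

    samples = [f"N{i+1:03d}" for i in range(n_norm)] + [
        f"T{i+1:03d}" for i in range(n_tum)
    ]
    condition = np.array(["normal"] * n_norm + ["tumor"] * n_tum)
    lane = rng.lognormal(0.0, 0.2, n_samples)

    rows, roles, names = [], [], []
    ladder = np.array([128.0, 32.0, 8.0, 2.0, 0.5, 0.125])[:n_pos_controls] * 100
    for i, conc in enumerate(ladder):
        rows.append(conc * lane * rng.lognormal(0, 0.05, n_samples))
        roles.append("positive_control")
        names.append(f"POS_{chr(65 + i)}")
    for i in range(n_neg_controls):
        rows.append(np.maximum(rng.normal(12, 4, n_samples), 0) * lane)
        roles.append("negative_control")
        names.append(f"NEG_{chr(65 + i)}")
    for i in range(n_housekeeping):
        mu = rng.uniform(300, 900)
        rows.append(mu * lane * rng.lognormal(0, noise_sd, n_samples))
        roles.append("housekeeping")
        names.append(f"HK_{i+1}")
    for i, fc in enumerate(effects):
        mu = target_mean * rng.lognormal(0, 0.4)
        sig = np.where(condition == "tumor", mu * fc, mu)
        rows.append(sig * lane * rng.lognormal(0, noise_sd, n_samples) + 10)
        roles.append("target")
        names.append(f"P{i+1}")
    if benchmark_effect is not None:
        mu = target_mean * 5
        sig = np.where(condition == "tumor", mu * benchmark_effect, mu)
        rows.append(sig * lane * rng.lognormal(0, noise_sd * 1.6, n_samples) + 10)
        roles.append("benchmark")
        names.append("BENCH")

    values = pd.DataFrame(np.vstack(rows), index=names, columns=samples)
    risk = np.where(
        condition == "tumor",
        rng.choice(["LR", "IR", "HR"], n_samples, p=[0.3, 0.35, 0.35]),
        "NA",
    )
    recurrence = np.where(
        condition == "tumor", rng.choice(["yes", "no"], n_samples, p=[0.25, 0.75]), "NA"
    )
    meta = pd.DataFrame(
        {"condition": condition, "risk": risk, "recurrence": recurrence}, index=samples
    )
    return ProbeTable(values, pd.Series(roles, index=names, name="role"), meta)
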