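import numpy as np
import pandas as pd
import pytest

from kmersig.contigs import (
    Contig,
    Alignment,
    align_contigs,
    assemble_contigs,
    catalog_to_bed12,
    categorize_alignment,
    classify_location,
    filter_catalog,
    overlap_fraction,
    window_dedup,
)
from kmersig.intervals import AnnotationIndex, GeneRecord, GenomicInterval
from kmersig.simulate import revcomp


def stats_frame(kmers, padj=None, lfc=None):
    n = len(kmers)
    return pd.DataFrame(
        {
            "padj": padj if padj is not None else [0.001] * n,
            "log2FC": lfc if lfc is not None else [2.0] * n,
        },
        index=list(kmers),
    )


class TestAssembly:
    def test_two_overlapping_kmers(self):
        ctgs = assemble_contigs(stats_frame(["ACGTA", "CGTAC"]), 5)
        assert len(ctgs) == 1
        assert ctgs[0].sequence == "ACGTAC"
        assert set(ctgs[0].member_kmers) == {"ACGTA", "CGTAC"}

    def test_self_loop_guarded(self):
        ctgs = assemble_contigs(stats_frame(["AAAAA"]), 5)
        assert len(ctgs) == 1
        assert ctgs[0].sequence == "AAAAA"

    def test_branch_stops_extension(self):
        # ACGTA -> CGTAC and CGTAG: branch, three separate contigs
        ctgs = assemble_contigs(stats_frame(["ACGTA", "CGTAC", "CGTAG"]), 5)
        assert sorted(c.sequence for c in ctgs) == ["ACGTA", "CGTAC", "CGTAG"]

    def test_representative_is_smallest_padj_ties_lexicographic(self):
        df = stats_frame(["ACGTA", "CGTAC", "GTACG"], padj=[0.01, 0.001, 0.001],
                         lfc=[1.0, 3.0, 2.0])
        (c,) = assemble_contigs(df, 5)
        assert c.representative_kmer == "CGTAC"  # ties 0.001: CGTAC < GTACG
        assert c.adjusted_p == 0.001
        assert c.log2_fold_change == 3.0

    def test_round_trip_random_sequences(self, rng):
        # 500 random 60-300 nt sequences; k-1 overlaps unique at k=31
        k = 31
        seqs = set()
        while len(seqs) < 500:
            L = int(rng.integers(60, 301))
            seqs.add("".join(rng.choice(list("ACGT"), L)))
        kmers = {}
        for s in seqs:
            for i in range(len(s) - k + 1):
                kmers[s[i : i + k]] = True
        ctgs = assemble_contigs(stats_frame(list(kmers)), k)
        # partition invariant
        assert sum(len(c.member_kmers) for c in ctgs) == len(kmers)
        reassembled = {c.sequence for c in ctgs}
        # every input sequence is recovered exactly (allowing for the rare
        # shared k-mer between sequences, which would split contigs)
        recovered = sum(s in reassembled for s in seqs)
        assert recovered / len(seqs) >= 0.99

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            assemble_contigs(stats_frame(["ACGT"]), 5)


class TestAlign:
    def make_genome(self, rng, n=5000):
        return {"chr1": "".join(rng.choice(list("ACGT"), n))}

    def test_unique_minus_strand_hit(self, rng):
        genome = self.make_genome(rng)
        sub = genome["chr1"][1000:1100]
        c = Contig("c", revcomp(sub), [], "", 0.001, 1.0)
        align_contigs([c], genome, k=31)
        assert len(c.alignments) == 1
        assert c.alignments[0].strand == "-"
        assert c.alignments[0].blocks == [(1000, 1100)]

    def test_unplaced_contig_empty_alignment(self, rng):
        genome = self.make_genome(rng)
        c = Contig("c", "".join(rng.choice(list("ACGT"), 80)), [], "", 0.001, 1.0)
        align_contigs([c], genome, k=31)
        assert c.alignments == []

    def test_spliced_two_block_alignment(self, rng):
        genome = self.make_genome(rng)
        g = genome["chr1"]
        contig_seq = g[500:600] + g[1400:1500]  # 800 bp intron
        c = Contig("c", contig_seq, [], "", 0.001, 1.0)
        align_contigs([c], genome, k=31)
        assert len(c.alignments) == 1
        blocks = c.alignments[0].blocks
        assert len(blocks) == 2
        gap = blocks[1][0] - blocks[0][1]
        assert gap == 800
        assert blocks[0][0] == 500 and blocks[1][1] == 1500

    def test_too_short_contig_raises(self, rng):
        genome = self.make_genome(rng)
        with pytest.raises(ValueError, match="shorter"):
            align_contigs([Contig("c", "ACGT", [], "", 0.5, 0.0)], genome, k=31)


class TestCategorize:
    def make(self, n_sites, n_blocks=1):
        c = Contig("c", "A" * 50, [], "", 0.001, 1.0)
        for i in range(n_sites):
            blocks = [(1000 * (i + 1), 1000 * (i + 1) + 25)]
            if n_blocks == 2:
                blocks.append((1000 * (i + 1) + 500, 1000 * (i + 1) + 525))
            c.alignments.append(Alignment("chr1", "+", blocks))
        return c

    def test_single_site_single_block_contiguous(self):
        assert categorize_alignment(self.make(1)) == "contiguous"

    def test_single_site_two_blocks_spliced(self):
        assert categorize_alignment(self.make(1, 2)) == "spliced"

    def test_multiplicity_beats_splicing(self):
        assert categorize_alignment(self.make(2, 2)) == "repeat"

    def test_no_sites_unmapped(self):
        assert categorize_alignment(self.make(0)) == "unmapped"


def make_annotation():
    return AnnotationIndex(
        [
            GeneRecord("pc", "chr1", 1000, 3000, "+", "protein_coding",
                       [(1000, 1400), (2600, 3000)]),
            GeneRecord("lnc", "chr1", 5000, 7000, "+", "lncRNA", [(5000, 7000)]),
        ]
    )


def located(start, end, strand):
    c = Contig("c", "A" * (end - start), [], "", 0.001, 1.0,
               alignments=[Alignment("chr1", strand, [(start, end)])])
    categorize_alignment(c)
    return c


class TestLocation:
    def test_sense_coding_exon_overlap(self):
        assert classify_location(located(1200, 1300, "+"), make_annotation()) == "coding"

    def test_intron_of_coding_gene_same_strand_is_not_coding(self):
        # gene-extent overlap without exon overlap: same-strand pc intron
        c = located(1500, 1600, "+")
        assert classify_location(c, make_annotation()) == "Inter"

    def test_lncrna_intron_same_strand_is_ol(self):
        assert classify_location(located(5500, 5600, "+"), make_annotation()) == "OL"

    def test_antisense_to_coding_exon(self):
        assert classify_location(located(1200, 1300, "-"), make_annotation()) == "AS"

    def test_antisense_to_lncrna(self):
        assert classify_location(located(5500, 5600, "-"), make_annotation()) == "AS"

    def test_no_overlap_inter(self):
        assert classify_location(located(9000, 9200, "+"), make_annotation()) == "Inter"

    def test_repeat_unassigned(self):
        c = located(1200, 1300, "+")
        c.alignments.append(Alignment("chr1", "+", [(8000, 8100)]))
        categorize_alignment(c)
        assert classify_location(c, make_annotation()) == "unassigned"

    def test_agrees_with_brute_force_scan(self, rng):
        genes = []
        for i in range(200):
            s = int(rng.integers(0, 95_000))
            e = s + int(rng.integers(200, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            bt = ["protein_coding", "lncRNA"][int(rng.integers(0, 2))]
            exons = [(s, (s + e) // 2), ((s + e) // 2 + 50, e)] if e - s > 400 else [(s, e)]
            genes.append(GeneRecord(f"g{i}", "chr1", s, e, strand, bt, exons))
        ann = AnnotationIndex(genes)
        for _ in range(300):
            qs = int(rng.integers(0, 95_000))
            qe = qs + int(rng.integers(50, 500))
            strand = "+" if rng.random() < 0.5 else "-"
            c = located(qs, qe, strand)
            got = classify_location(c, ann)
            # brute force with the same precedence
            iv = GenomicInterval("chr1", qs, qe, strand)
            same = [g for g in genes if g.strand == strand and g.interval.overlaps(iv)]
            opp = [g for g in genes if g.strand != strand and g.interval.overlaps(iv)]
            coding = any(
                g.biotype == "protein_coding"
                and any(min(e1, qe) > max(s1, qs) for s1, e1 in g.exons)
                for g in same
            )
            if coding:
                want = "coding"
            elif any(g.biotype == "lncRNA" for g in same):
                want = "OL"
            elif opp:
                want = "AS"
            else:
                want = "Inter"
            assert got == want, (qs, qe, strand)


class TestFilterAndDedup:
    def make(self, cid, length, padj, location="Inter", category="contiguous",
             start=None):
        c = Contig(cid, "A" * length, [], "", padj, 1.0)
        if category != "unmapped":
            s = start if start is not None else 1000
            c.alignments = [Alignment("chr1", "+", [(s, s + length)])]
        c.category = category
        c.location = location if category in ("contiguous", "spliced") else "unassigned"
        return c

    def test_length_boundary_strict(self):
        kept = filter_catalog([self.make("a", 200, 0.001), self.make("b", 201, 0.001)])
        assert [c.contig_id for c in kept] == ["b"]

    def test_padj_boundary_strict(self):
        kept = filter_catalog([self.make("a", 250, 0.01), self.make("b", 250, 0.009)])
        assert [c.contig_id for c in kept] == ["b"]

    def test_coding_excluded_regardless_of_p(self):
        kept = filter_catalog([self.make("a", 250, 1e-30, location="coding")])
        assert kept == []

    def test_unmapped_kept_by_default_category_whitelist(self):
        kept = filter_catalog([self.make("a", 250, 0.001, category="unmapped")])
        assert len(kept) == 1
        kept = filter_catalog(
            [self.make("a", 250, 0.001, category="unmapped")],
            keep_categories={"contiguous"},
        )
        assert kept == []

    def test_window_dedup_within_and_beyond(self):
        a = self.make("a", 250, 1e-5, start=1000)
        b = self.make("b", 250, 1e-3, start=4250)  # 3 kb gap from a's end
        kept = window_dedup([a, b], window=5000)
        assert [c.contig_id for c in kept] == ["a"]
        c2 = self.make("c", 250, 1e-3, start=7300)  # 6.05 kb gap
        kept = window_dedup([a, c2], window=5000)
        assert [c.contig_id for c in kept] == ["a", "c"]

    def test_window_dedup_single_linkage_chain(self):
        # a-b 4 kb, b-c 4 kb, a-c ~8.5 kb: one survivor for the chain
        a = self.make("a", 250, 1e-5, start=1000)
        b = self.make("b", 250, 1e-6, start=5250)
        c = self.make("c", 250, 1e-4, start=9500)
        kept = window_dedup([a, b, c], window=5000)
        assert [x.contig_id for x in kept] == ["b"]

    def test_unmapped_pass_through(self):
        a = self.make("a", 250, 1e-5)
        u = self.make("u", 250, 0.5, category="unmapped")
        kept = window_dedup([a, u], window=5000)
        assert {x.contig_id for x in kept} == {"a", "u"}

    def test_bed12_export(self):
        a = self.make("a", 250, 1e-5, start=100)
        recs = catalog_to_bed12([a])
        assert recs[0].name == "a" and recs[0].blocks == [(100, 350)]


class TestOverlapFraction:
    def iv(self, s, e, strand="+"):
        return GenomicInterval("chr1", s, e, strand)

    def test_boundary_inclusive(self):
        pairs = overlap_fraction([self.iv(0, 100)], [self.iv(50, 200)], 0.5)
        assert pairs == [(0, 0)]

    def test_reciprocal_mode(self):
        pairs = overlap_fraction([self.iv(0, 100)], [self.iv(60, 200)], 0.5,
                                 reciprocal=True)
        assert pairs == []
        # one-directional: 40/100 < 0.5 either way
        assert overlap_fraction([self.iv(0, 100)], [self.iv(60, 200)], 0.4) == [(0, 0)]

    def test_disjoint_and_strand(self):
        assert overlap_fraction([self.iv(0, 100)], [self.iv(200, 300)], 0.5) == []
        assert overlap_fraction([self.iv(0, 100, "+")], [self.iv(0, 100, "-")], 0.5) == []
        assert overlap_fraction([self.iv(0, 100, "+")], [self.iv(0, 100, "-")], 0.5,
                                stranded=False) == [(0, 0)]
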