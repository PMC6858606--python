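import numpy as np
import pandas as pd
import pysam
import pytest

from kmersig.intervals import AnnotationIndex, Bed12Record, GeneRecord, GenomicInterval
from kmersig.simulate import SimConfig, make_reference, plant_events, simulate_reads
from kmersig.tu import (
    Junction,
    JunctionSet,
    assign_classes,
    classify_tu,
    count_in_features,
    coverage_segments,
    extract_junctions,
    merge_segments,
    rpkm,
    rpkm_matrix,
)


def write_sam(path, reads, chrom_len=100_000):
    """reads: list of (name, start, cigar, flag, mate_start, mapq)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": chrom_len}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        segs = []
        for name, start, cigar, flag, mate_start, mapq in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = cigar
            a.flag = flag
            a.mapping_quality = mapq
            ln = sum(n for op, n in a.cigartuples if op in (0, 1, 4))
            a.query_sequence = "A" * ln
            a.next_reference_id = 0
            a.next_reference_start = mate_start
            segs.append(a)
        segs.sort(key=lambda s: s.reference_start)
        for s in segs:
            fh.write(s)
    return str(path)


# flags: paired|proper|read1 = 1+2+64 = 67 (+16 rev = 83); read2 = 1+2+128 = 131 (+16 = 147)
R1F, R1R, R2F, R2R = 67 | 32, 83, 131, 147 | 32  # mate-strand bits approximate


def stack(path, n, start=1000, read_len=100, flag=83, mapq=60):
    """n identical single-mate records (paired flags but mate ignored)."""
    reads = [(f"r{i}", start, f"{read_len}M", flag, start, mapq) for i in range(n)]
    return write_sam(path, reads)


class TestCoverageSegments:
    def test_support_threshold_met_in_one_sample(self, tmp_path):
        # 12 reads stacked in sample 1, none elsewhere: retained
        s1 = stack(tmp_path / "s1.sam", 12)
        s2 = write_sam(tmp_path / "s2.sam", [])
        segs = coverage_segments({"s1": s1, "s2": s2}, min_reads=10)
        # flag 83: read1 reverse => fr-firststrand transcript strand '+'
        assert ("chr1", "+") in segs
        assert segs[("chr1", "+")] == [(1000, 1100)]

    def test_below_threshold_everywhere_dropped(self, tmp_path):
        s1 = stack(tmp_path / "s1.sam", 9)
        s2 = stack(tmp_path / "s2.sam", 9)
        segs = coverage_segments({"s1": s1, "s2": s2}, min_reads=10)
        assert segs == {}

    def test_union_across_samples(self, tmp_path):
        s1 = stack(tmp_path / "s1.sam", 12, start=1000)
        s2 = stack(tmp_path / "s2.sam", 12, start=1050)
        segs = coverage_segments({"s1": s1, "s2": s2}, min_reads=10)
        assert segs[("chr1", "+")] == [(1000, 1150)]

    def test_mapq_filter(self, tmp_path):
        s1 = stack(tmp_path / "s1.sam", 12, mapq=10)
        segs = coverage_segments({"s1": s1}, min_reads=10, min_mapq=50)
        assert segs == {}

    def test_unsorted_input_raises(self, tmp_path):
        path = tmp_path / "u.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10_000}]}
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for start in (500, 100):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = f"r{start}"
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = "50M"
                a.flag = 83
                a.query_sequence = "A" * 50
                a.mapping_quality = 60
                fh.write(a)
        with pytest.raises(ValueError, match="sort"):
            coverage_segments({"s": str(path)}, min_reads=1)


class TestMergeSegments:
    def test_gap_99_merges(self):
        assert merge_segments([(100, 300), (399, 600)], 100) == [(100, 600)]

    def test_gap_100_does_not_merge(self):
        assert merge_segments([(100, 300), (400, 600)], 100) == [(100, 300), (400, 600)]

    def test_opposite_strands_never_merged(self):
        segs = {("chr1", "+"): [(100, 300)], ("chr1", "-"): [(300, 500)]}
        out = merge_segments(segs, 100)
        assert out[("chr1", "+")] == [(100, 300)]
        assert out[("chr1", "-")] == [(300, 500)]

    def test_idempotent(self, rng):
        ivs = [(int(s), int(s) + int(l)) for s, l in
               zip(rng.integers(0, 10_000, 500), rng.integers(1, 300, 500))]
        once = merge_segments(ivs, 100)
        assert merge_segments(once, 100) == once

    def test_matches_brute_force_on_random_intervals(self, rng):
        starts = rng.integers(0, 200_000, 10_000)
        lens = rng.integers(1, 150, 10_000)
        ivs = list(zip(starts.tolist(), (starts + lens).tolist()))
        got = merge_segments(ivs, 100)
        # brute force transitive closure
        ivs_s = sorted(ivs)
        ref = [list(ivs_s[0])]
        for s, e in ivs_s[1:]:
            if s - ref[-1][1] <= 99:
                ref[-1][1] = max(ref[-1][1], e)
            else:
                ref.append([s, e])
        assert got == [tuple(x) for x in ref]
        assert all(b[0] - a[1] >= 100 for a, b in zip(got, got[1:]))


class TestClassifyTu:
    def ann(self):
        return AnnotationIndex(
            [GeneRecord("g", "chr1", 1000, 3000, "+", "protein_coding", [(1000, 3000)]),
             GeneRecord("l", "chr1", 8000, 9000, "+", "lncRNA", [(8000, 9000)])]
        )

    def test_antisense_retained(self):
        tus = classify_tu({("chr1", "-"): [(1500, 2000)]}, self.ann())
        assert len(tus) == 1 and tus[0].context == "antisense"

    def test_short_intergenic_dropped(self):
        tus = classify_tu({("chr1", "+"): [(5000, 5150)]}, self.ann())
        assert tus == []

    def test_sense_overlap_with_lncrna_excluded(self):
        tus = classify_tu({("chr1", "+"): [(8100, 8600)]}, self.ann())
        assert tus == []
        tus = classify_tu({("chr1", "+"): [(8100, 8600)]}, self.ann(),
                          keep_sense_overlap=True)
        assert tus[0].context == "sense_overlap"

    def test_length_boundary_strict(self):
        tus = classify_tu({("chr1", "+"): [(5000, 5200)]}, self.ann())
        assert tus == []
        tus = classify_tu({("chr1", "+"): [(5000, 5201)]}, self.ann())
        assert len(tus) == 1 and tus[0].context == "intergenic"


class TestCountInFeatures:
    def feature(self, s, e, strand="+"):
        return [("f1", GenomicInterval("chr1", s, e, strand))]

    def pair(self, path, start1=1000, start2=1150, r1rev=True):
        f1 = 83 if r1rev else 67 | 32
        f2 = (131 | 32) if r1rev else 147
        reads = [("p", start1, "100M", f1, start2, 60),
                 ("p", start2, "100M", f2, start1, 60)]
        return write_sam(path, reads)

    def test_proper_pair_counts_one_fragment(self, tmp_path):
        sam = self.pair(tmp_path / "a.sam")
        out = count_in_features({"s": sam}, self.feature(900, 1400))
        assert out.loc["f1", "s"] == 1

    def test_multi_overlap_increments_both(self, tmp_path):
        sam = self.pair(tmp_path / "a.sam")
        feats = [("f1", GenomicInterval("chr1", 900, 1400, "+")),
                 ("f2", GenomicInterval("chr1", 1100, 1600, "+"))]
        out = count_in_features({"s": sam}, feats, multi_overlap=True)
        assert out["s"].tolist() == [1, 1]
        out = count_in_features({"s": sam}, feats, multi_overlap=False)
        assert out["s"].tolist() == [0, 0]

    def test_reverse_strandedness_rule(self, tmp_path):
        # mate1 reverse => fragment '+' under -s 2
        sam = self.pair(tmp_path / "a.sam", r1rev=True)
        plus = count_in_features({"s": sam}, self.feature(900, 1400, "+"))
        minus = count_in_features({"s": sam}, self.feature(900, 1400, "-"))
        assert plus.loc["f1", "s"] == 1
        assert minus.loc["f1", "s"] == 0
        # sense-oriented mate1 => fragment '-': '+' feature not counted
        sam2 = self.pair(tmp_path / "b.sam", r1rev=False)
        plus2 = count_in_features({"s": sam2}, self.feature(900, 1400, "+"))
        assert plus2.loc["f1", "s"] == 0

    def test_empty_features_error(self, tmp_path):
        sam = self.pair(tmp_path / "a.sam")
        with pytest.raises(ValueError):
            count_in_features({"s": sam}, [])


class TestRpkm:
    def test_unit_definition(self):
        assert rpkm(10, 1000, 10**6) == pytest.approx(10.0)

    def test_zero_count(self):
        assert rpkm(0, 500, 10**6) == 0.0

    def test_doubling_total_halves(self):
        assert rpkm(10, 1000, 2 * 10**6) == pytest.approx(rpkm(10, 1000, 10**6) / 2)

    def test_matrix_form(self):
        counts = pd.DataFrame([[10, 20]], index=["f"], columns=["a", "b"])
        out = rpkm_matrix(counts, {"f": 1000}, {"a": 10**6, "b": 10**6})
        assert out.loc["f"].tolist() == [10.0, 20.0]


class TestAssignClasses:
    def setup_case(self, tu_expr, n_junc, n_est):
        from kmersig.tu import TranscriptionUnit

        tu = TranscriptionUnit("TU_0", GenomicInterval("chr1", 1000, 2000, "+"))
        tu_rpkm = pd.DataFrame({"a1": [tu_expr], "a2": [tu_expr],
                                "b1": [tu_expr], "b2": [tu_expr]}, index=["TU_0"])
        # mRNA distribution: 20th percentile of means = 2.0 approximately
        mrna = pd.DataFrame(
            np.tile(np.linspace(1, 10, 10)[:, None], (1, 4)),
            index=[f"g{i}" for i in range(10)], columns=["a1", "a2", "b1", "b2"],
        )
        conds = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        js = JunctionSet()
        for i in range(n_junc):
            js.add(Junction("chr1", 1200 + i, 1500 + i, "+"))
        ests = [Bed12Record("chr1", 900, 2100, "e", "+", [(900, 1300), (1800, 2100)])] * n_est
        assign_classes([tu], tu_rpkm, mrna, conds, js, ests)
        return tu

    def test_class1_requires_junction_and_est(self):
        assert self.setup_case(50.0, 1, 1).tu_class == "class1"

    def test_class2_without_junction(self):
        assert self.setup_case(50.0, 0, 1).tu_class == "class2"

    def test_below_threshold(self):
        assert self.setup_case(0.1, 1, 1).tu_class == "below_threshold"

    def test_empty_mrna_errors(self):
        from kmersig.tu import TranscriptionUnit

        tu = TranscriptionUnit("TU_0", GenomicInterval("chr1", 0, 100, "+"))
        with pytest.raises(ValueError, match="mRNA"):
            assign_classes([tu], pd.DataFrame({"a": [1.0]}, index=["TU_0"]),
                           pd.DataFrame(), {"a": "A"}, JunctionSet(), [])

    def test_junction_strand_must_match(self):
        tu = self.setup_case(50.0, 0, 1)
        js = JunctionSet({Junction("chr1", 1200, 1500, "-"): 3})
        assert js.within(tu.interval) == []


class TestJunctionExtraction:
    def test_junctions_from_gapped_alignments(self, tmp_path):
        reads = [(f"r{i}", 1000, "50M200N50M", 83, 1000, 60) for i in range(3)]
        sam = write_sam(tmp_path / "j.sam", reads)
        js = extract_junctions({"s": sam})
        assert len(js) == 1
        j = next(iter(js.support))
        assert (j.donor_end, j.acceptor_start, j.strand) == (1050, 1250, "+")
        assert js.support[j] == 3


class TestSyntheticRecovery:
    def test_planted_tu_span_recovery(self, small_cfg, small_reference,
                                      small_truth, small_sam_dir):
        segs = merge_segments(coverage_segments(small_sam_dir, min_reads=10), 100)
        ann = AnnotationIndex(small_reference.genes)
        tus = classify_tu(segs, ann)
        for ev in small_truth.events:
            best = 0.0
            for t in tus:
                if (t.interval.strand == ev.strand
                        and t.interval.overlaps(ev.interval)):
                    best = max(best,
                               t.interval.overlap_length(ev.interval) / len(ev.interval))
            assert best >= 0.8, f"{ev.event_id} covered only {best:.2f}"
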