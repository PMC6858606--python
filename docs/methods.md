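# Methods

`kmersig` implements a reference-free RNA biomarker discovery workflow for
two-condition stranded RNA-seq studies, together with the reference-based
and statistical stages needed to carry a candidate from raw reads to an
evaluated multiplex signature. This note records the models, the defaults
and why they hold, the numerical choices, and what the synthetic cohorts do
and do not establish.

## Discovery: differential k-mers to a contig catalog

Reads are decomposed into k-mers (default k = 31) in transcript orientation:
under the fr-firststrand (dUTP) protocol mate 1 is reverse-complemented and
mate 2 taken as-is. k-mers exactly matching an annotated transcript set are
masked, same strand only — a strand-agnostic mask would annihilate the
antisense class that the workflow exists to find. Per-sample counts are
joined under a recurrence filter (count ≥ 5 in ≥ 6 samples by default,
evaluated jointly over both conditions), matching the single-parameter
semantics of the discovery run it reproduces.

Each retained k-mer is tested for differential abundance with a per-row
negative-binomial Wald test: normalized counts q_ij = c_ij / s_j, a
method-of-moments dispersion pooled over within-condition variances and
floored at 1e-8, and a Wald statistic on log2 FC (pseudocount 0.5 on the
means, used in the fold change only, never in the testing counts). This is a
deliberate desk-scale stand-in for a full shrinkage-based NB framework: no
dispersion sharing across rows, no outlier filtering. Its type-I error under
the NB null (μ = 50, α = 0.2, 8 vs 16 samples) is measured at ~0.05–0.06,
within the 0.03–0.07 calibration band the package tests. A Welch t-test on
log2(q + 1) is available as an alternative mode. Benjamini–Hochberg controls
FDR; all p-value thresholds are strict ("below 0.01" means `<`).

Size factors: the median-of-ratios procedure is used for ordinary feature
count matrices. For the masked, recurrence-filtered k-mer matrix the rows
are dominated by condition-specific signal and median-of-ratios would
normalize the signal away, so the discovery pipeline instead derives size
factors from library depth (total counted k-mers before masking), scaled to
geometric mean 1. Median-of-ratios factors are defined up to a common
constant (the geometric-mean pseudo-reference rescales); their ratios are
scale-equivariant, which is the property tests assert.

Significant k-mers (adjusted p < 0.05, up-regulated) are assembled into
unitigs: maximal non-branching paths in the (k−1)-overlap graph, extension
stopping at any branch, self-loops guarded. This is deterministic and keeps
every contig a substring of a real transcript; every DE k-mer belongs to
exactly one contig. The representative k-mer is the member with the smallest
adjusted p (ties lexicographic) and the contig inherits its statistics.

The internal aligner is exact-match only, plus a single two-block split
(longest exact prefix + longest exact suffix, same chromosome and strand,
gap ≤ 300 kb, both blocks ≥ k) to capture spliced contigs; real-genome use
consumes external BED12 alignments. Categories: unmapped, repeat (> 1
genomic site — multiplicity takes precedence over splicing, since it
invalidates the unique-fragment reading), spliced, contiguous. Locations
use the precedence coding > OL > AS > Inter, with gene extents for OL/AS/
Inter and exon-level overlap only for the coding exclusion, so intronic
contigs of noncoding genes stay in the catalog. The catalog keeps noncoding
locations with length > 200 nt and adjusted p < 0.01 (both strict). The 5-kb
window deduplication clusters mapped contigs by single linkage on their
alignment spans and keeps the lowest adjusted p per cluster.

## Reference-based transcription units

Uniquely mapped reads (MAPQ ≥ 50 by default) are piled into per-strand
coverage; covered intervals are unioned across samples and retained when
supported by ≥ 10 reads in at least one sample, then merged when separated
by less than 100 nt (gap 99 merges, gap 100 does not). Segments overlapping
a same-strand gene are sense-overlap and excluded from the lncRNA catalog;
the rest are antisense or intergenic, retained above 200 nt. TUs are
single-interval coverage objects, not exon-chained models — the protocol
merges coverage, it does not infer isoform structure.

Fragments (not mates) are counted per feature with reverse strandedness
(fragment strand = opposite of mate 1) and multi-overlap crediting, the
conventions of `featureCounts -p -s 2 -O`. Expression is RPKM. Class 2
requires condition-level expression (mean across the condition's samples;
max available via config) strictly above the 0.2 quantile (type-7) of the
mRNA RPKM distribution in at least one condition; Class 1 additionally
requires ≥ 1 exon–exon junction (parsed from gapped alignments, ≥ 1
supporting read, both ends inside the TU on its strand) and ≥ 1 spliced EST
overlapping the TU.

## Quantification in independent libraries

Contigs are quantified by their representative k-mer and by k-mers sampled
along the contig, restricted to k-mers occurring at most once in a reference
transcript set (0 = novel, 1 = unambiguous; "exactly once" is switchable).
Sampling is deterministic: n = 10 positions p_i = round(0.1(L−1) +
i·0.8(L−1)/9) along the unique-k-mer list, with four replicates shifting the
indices by 0–3 (clamped, deduplicated). Counting is a single streaming pass;
unstranded libraries credit a k-mer or its reverse complement, stranded
libraries the sense form only. Counts are normalized per million reads.
Concordance between representative and mean-sampled counts is summarized per
contig by Pearson r across libraries (missing when a vector is constant).

## Probe statistics

Multiplex counting tables are normalized in three steps: lane scaling by
positive-control geometric means, negative-control background subtraction
floored at 0.5 (absolute; rows at the floor are the one place lane-scale
invariance deliberately breaks), and content normalization by the arithmetic
mean of housekeeping probes. The exact vendor normalization is proprietary
and unpublished; this fixed three-step scheme reproduces its documented
intent.

Probes are tested with a two-sided Wilcoxon rank-sum: exact enumeration when
both groups have ≤ 8 samples and no ties, otherwise a refined normal
approximation — continuity-corrected with an Edgeworth kurtosis term,
γ₂ = −(6/5)(m²+n²+mn+m+n)/(mn(m+n+1)), exact for tie-free data. The plain
continuity-corrected normal leaves mid-range two-sided errors up to 0.011 at
m = n = 8; the kurtosis term brings the worst case below 0.001. With ties the
tie-corrected normal approximation is used. Fold changes are ratios of group
means (pseudocount 0.5 when a mean is zero). Ranking is by ascending p, ties
by descending FC, with strict significance cuts and a benchmark-relative
flag.

Risk stratification is rule-table-driven data, not code: first-match rows
with inclusive Gleason/TNM bounds, PSA deliberately excluded. The shipped
default marks Gleason ≥ 8 or stage ≥ T2c as high risk, Gleason ≤ 6 and
stage ≤ T2a as low risk, the remainder intermediate.

## Signature inference and evaluation

Class imbalance (9 normal vs 135 tumor in the selection design) is corrected
by upsampling the minority class with replacement, training data only.
Probe selection is L1-penalized logistic regression fit by IRLS coordinate
descent with soft-thresholding on internally standardized columns, a
100-point log-spaced λ path from λ_max down to 10⁻³ λ_max, and λ chosen by
10-fold cross-validated binomial deviance under the 1-SE rule (CV-min
available). Stability selection repeats this on B subsamples (50% of rows
without replacement, redrawn to contain both classes, then upsampled) and
retains probes selected in strictly more than half the runs. B defaults to
2000; the shipped acceptance workflow uses B = 300, which this problem size
(24 probes) comfortably saturates. One behavior worth knowing: when many
probes carry the *same* strong signal, the parsimonious 1-SE fits spread
selection across them and individual probabilities can fall below 0.5 —
stability selection under redundancy keeps a representative subset, not
every redundant probe.

The classifier is LogitBoost with single-feature threshold stumps:
p = 1/(1+e^(−2F)), working response z = (y−p)/(p(1−p)) with p clipped to
[10⁻⁵, 1−10⁻⁵] and z to ±4, best stump by weighted least squares, F
advanced by half the stump. Ties in stump error resolve to the lowest
feature index, then the lowest threshold. The iteration count (≤ 100) is
tuned by leave-one-out accuracy over a grid (step 5), ties to the fewest
iterations. It is exposed as a sklearn-compatible estimator
(`LogitBoostClassifier`) and composes with sklearn model selection.

Evaluation repeats stratified 70/30 splits (default 100), upsampling and
refitting the classifier per training split — signature membership, never
fitted coefficients, transfers between cohorts — and reports per-split AUC
(tie-aware Mann–Whitney U / n₁n₂), their mean and SD, and the vertically
averaged ROC on a fixed 101-point FPR grid.

## Synthetic cohorts

The generator builds a 1 Mb single-chromosome genome with 200 multi-exon
gene models (70% protein-coding), plants 20 unannotated events (intergenic
and antisense lncRNAs by default; exon extensions and novel splice variants
on request) with fold changes drawn uniformly on log2 between 6 and 12, and
simulates 8 vs 16 stranded paired-end libraries: per-transcript fragment
counts are gamma-Poisson (NB) with dispersion 0.1 around lognormal gene
means (mean 10 fragments/sample; event baseline 6), fragments ~N(250, 40)
bp, 100-bp reads, substitution errors at 0.005/base, constant quality.
Alignments are emitted from the known fragment coordinates — no aligner runs
— which exercises SAM parsing, strand inference and junction extraction with
exact ground truth. Everything is deterministic under the seed
(`numpy.random.default_rng`).

What this does not emulate: real genome repeat structure and homology (the
random genome makes 31-mers nearly always unique, so the repeat category is
exercised only by construction), indels and quality-dependent errors,
fragment GC bias, positional coverage bias, incomplete annotation, and
batch effects. Passing recovery tests therefore demonstrates the logic of
the pipeline — counting, masking, testing, assembly, classification — under
controlled conditions, not its yield on human tissue data.

Probe tables emulate a NanoString-style layout: a positive-control ladder,
negative-control background, six housekeeping probes without class effect,
and target probes with planted tumor/normal fold changes under lognormal
noise (σ = 0.35) and per-lane scale factors; a small additive background
(+10 counts) keeps zeros away from the ratio steps.

## Problem sizes and runtime

The shipped tests and the acceptance script use the study's stated design
dimensions where they exist (8 vs 16 discovery samples; 24 candidate probes;
144-sample selection cohort at 9:135; 557-sample validation cohort at
52:505; 100 evaluation splits) and desk-scale choices elsewhere (1 Mb
genome, 20 planted events, B = 300 stability subsamples, 30 splits for the
permuted-label control, 5 informative probes within the workflow's 5–9
range). The inner numerical loops (LASSO path, LogitBoost, LOOCV) are
numba-jitted; the full acceptance run completes in minutes on one CPU.

## Known limitations

- The NB Wald test is per-row; at very low counts or tiny group sizes its
  calibration band is wider than a shrinkage-based implementation's.
- The internal contig aligner handles at most one split and no mismatches;
  divergent or multi-intron contigs need an external aligner (BED12 input).
- TU assembly reports coverage intervals, not isoforms; overlapping
  same-strand transcripts merge into one TU.
- Stability-selection probabilities are interpretable per probe only when
  probes are not mutually redundant (see above).
- The simulator's uniform random genome understates multi-mapping; repeat
  handling is tested structurally, not statistically.
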