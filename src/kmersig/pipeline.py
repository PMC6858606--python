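"""In-memory orchestration of the reference-free discovery phase."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .contigs import (
    Contig,
    align_contigs,
    assemble_contigs,
    categorize_alignment,
    classify_location,
    filter_catalog,
)
from .diffexp import SampleDesign, nb_wald_test, select_de_kmers, size_factors_from_totals
from .intervals import AnnotationIndex
from .kmers import apply_mask, build_mask, count_kmers, join_samples
from .simulate import Reference, SimulatedCohort


@dataclass
class DiscoveryResult:
    joined_rows: int
    de_results: pd.DataFrame
    de_kmers: pd.DataFrame
    contigs: list[Contig]
    catalog: list[Contig]


def discover_catalog(
    cohort: SimulatedCohort,
    reference: Reference,
    k: int = 31,
    protocol: str = "fr-firststrand",
    min_recurrence: int = 6,
    min_recurrence_abundance: int = 5,
    p_threshold: float = 0.05,
    direction: str = "up",
    min_length: int = 200,
    max_adjusted_p: float = 0.01,
) -> DiscoveryResult:
    """Run reads -> masked k-mer matrix -> DE test -> contig catalog.

    Size factors come from library depth (total counted k-mers before
    masking): after masking and recurrence filtering the matrix is dominated
    by condition-specific rows, on which median-of-ratios would normalize the
    signal away.
    """
    mask = build_mask(reference.transcripts.values(), k)
    tables, totals = [], []
    for sid in cohort.sample_ids:
        t = count_kmers(
            ((rp.seq1, rp.seq2) for rp in cohort.reads[sid]), k, protocol, sid
        )
        totals.append(t.total())
        tables.append(apply_mask(t, mask))
    joined = join_samples(tables, min_recurrence, min_recurrence_abundance)
    design = SampleDesign(
        cohort.sample_ids,
        [cohort.conditions[s] for s in cohort.sample_ids],
        totals,
    )
    matrix = joined.to_frame()
    res = nb_wald_test(matrix, design, size_factors=size_factors_from_totals(totals))
    de = select_de_kmers(res, p_threshold, direction)
    contigs = assemble_contigs(de, k)
    align_contigs(contigs, reference.genome, k=k)
    ann = AnnotationIndex(reference.genes)
    for c in contigs:
        categorize_alignment(c)
        classify_location(c, ann)
    catalog = filter_catalog(contigs, min_length, max_adjusted_p)
    return DiscoveryResult(len(matrix), res, de, contigs, catalog)


def event_recovery(truth, catalog: list[Contig]) -> dict[str, bool]:
    """Which planted events have a catalog contig overlapping them with the
    expected location label (Inter for intergenic-type events, AS for
    antisense events)."""
    expected = {
        "intergenic_lnc": "Inter",
        "splice_variant": "Inter",
        "exon_extension": None,  # extension location depends on context
        "antisense_lnc": "AS",
    }
    out = {}
    for ev in truth.events:
        want = expected[ev.type]
        hit = False
        for c in catalog:
            if not c.alignments:
                continue
            sp = c.primary.span
            if (
                sp.overlaps(ev.interval)
                and c.primary.strand == ev.strand
                and (want is None or c.location == want)
            ):
                hit = True
                break
        out[ev.event_id] = hit
    return out
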