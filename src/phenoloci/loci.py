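"""Locus (SOR) derivation from overlapping patient CNVs.

A locus — a small overlapping region, SOR — is a maximal genomic segment
covered by a constant set of patient CNVs.  Segmentation collects every
CNV breakpoint on a chromosome, forms the elementary intervals between
consecutive breakpoints, attaches the covering CNV set to each, drops
uncovered gaps, and merges adjacent segments whose CNV sets are equal.
The resulting loci partition the covered genome: within one variant
class and chromosome they are disjoint, and adjacent loci differ in
their supporting CNVs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .cohort import CNVRecord, GenomicInterval, VariantClass


@dataclass(frozen=True)
class Locus:
    """A maximal constant-coverage segment and its supporting CNVs."""

    locus_id: str
    interval: GenomicInterval
    cnv_ids: frozenset[str]
    patient_ids: frozenset[str]
    variant_class: VariantClass


@dataclass(frozen=True)
class LocusHit:
    """A query CNV's overlap with one reference locus.

    ``locus_overlap_pct`` is the share of the *locus* covered by the
    query (in bp): 100% means the query CNV contains the whole locus.
    """

    locus: Locus
    overlap_bp: int
    locus_overlap_pct: float


def segment_sors(cnvs: Sequence[CNVRecord]) -> list[Locus]:
    """Segment CNVs of one variant class into loci (SORs).

    All records must share one variant class; deletions and duplications
    form separate subnetworks and are segmented independently.  Output is
    sorted by (chrom, start).  Empty input yields an empty list.
    """
    if not cnvs:
        return []
    classes = {c.variant_class for c in cnvs}
    if len(classes) > 1:
        raise ValueError(f"mixed variant classes in one segmentation: "
                         f"{sorted(c.value for c in classes)}")
    vclass = classes.pop()

    by_chrom: dict[str, list[CNVRecord]] = {}
    for c in cnvs:
        by_chrom.setdefault(c.interval.chrom, []).append(c)

    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        recs = by_chrom[chrom]
        points = sorted({p for r in recs for p in (r.interval.start, r.interval.end)})
        # elementary intervals between consecutive breakpoints, with covers
        segments: list[tuple[int, int, frozenset[str]]] = []
        for a, b in zip(points, points[1:]):
            cover = frozenset(
                r.cnv_id for r in recs
                if r.interval.start <= a and r.interval.end >= b
            )
            if cover:
                segments.append((a, b, cover))
        # merge adjacent segments with identical CNV sets
        merged: list[tuple[int, int, frozenset[str]]] = []
        for a, b, cover in segments:
            if merged and merged[-1][1] == a and merged[-1][2] == cover:
                merged[-1] = (merged[-1][0], b, cover)
            else:
                merged.append((a, b, cover))
        owners = {r.cnv_id: r.patient_id for r in recs}
        for a, b, cover in merged:
            loci.append(Locus(
                locus_id=f"{chrom}:{a}-{b}",
                interval=GenomicInterval(chrom, a, b),
                cnv_ids=cover,
                patient_ids=frozenset(owners[c] for c in cover),
                variant_class=vclass,
            ))
    return loci


def map_query(loci: Sequence[Locus], query: GenomicInterval) -> list[LocusHit]:
    """Find every locus overlapping ``query`` by at least one bp.

    Returns hits sorted by genomic position, each annotated with the
    overlap in bp and the percentage of the locus covered by the query.
    No overlap (the unmatched-case situation) yields an empty list.
    """
    hits: list[LocusHit] = []
    for locus in loci:
        bp = locus.interval.overlap_bp(query)
        if bp >= 1:
            hits.append(LocusHit(
                locus=locus,
                overlap_bp=bp,
                locus_overlap_pct=100.0 * bp / locus.interval.length,
            ))
    hits.sort(key=lambda h: (h.locus.interval.chrom, h.locus.interval.start))
    return hits


def unmatched_region(
    hits: Iterable[LocusHit], query: GenomicInterval
) -> list[GenomicInterval]:
    """Parts of the query not covered by any hit locus, as maximal intervals.

    These are candidate novel pathogenic regions: stretches of the query
    CNV with no precedent in the reference network.
    """
    covered = sorted(
        (max(h.locus.interval.start, query.start),
         min(h.locus.interval.end, query.end))
        for h in hits
        if h.locus.interval.chrom == query.chrom
    )
    out: list[GenomicInterval] = []
    cursor = query.start
    for a, b in covered:
        if a > cursor:
            out.append(GenomicInterval(query.chrom, cursor, a))
        cursor = max(cursor, b)
    if cursor < query.end:
        out.append(GenomicInterval(query.chrom, cursor, query.end))
    return out


def write_bed(loci: Iterable[Locus], stream: TextIO) -> None:
    """Export loci as BED (0-based half-open) with CNV and patient counts."""
    for l in loci:
        stream.write(
            f"{l.interval.chrom}\t{l.interval.start}\t{l.interval.end}\t"
            f"{l.locus_id}\t{len(l.cnv_ids)}\t{len(l.patient_ids)}\n"
        )
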