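"""Phenotype ranking and clinical reports for novel CNV cases.

A query CNV from an uncharacterized patient is mapped onto the reference
loci by genomic overlap; for each overlapped locus the phenotypes are
ranked by their HyI association to that locus.  Each ranked row carries
penetrance, % max and the locus-overlap percentage, and is marked "+"
(most specific term among those reported) or "->" (parental term).
Ranked output is compared against the clinician's observed phenotypes,
and cohorts of cases are summarized as a phenotype-by-patient grid with
two significance tiers.

Query patients are scored against the pre-built reference network and
never added to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .association import AssociationScore, DEFAULT_THRESHOLD
from .cohort import CNVRecord, GenomicInterval
from .loci import Locus, LocusHit, map_query, unmatched_region
from .ontology import Ontology, most_specific, propagate


class Marker(str, Enum):
    SPECIFIC = "+"
    PARENTAL = "->"


class GridTier(str, Enum):
    DIAGNOSED_AND_SIGNIFICANT = "diagnosed_and_significant"
    DIAGNOSED_AND_DETECTED_BELOW_THRESHOLD = "diagnosed_and_detected_below_threshold"
    DIAGNOSED_ONLY = "diagnosed_only"
    PREDICTED_ONLY = "predicted_only"
    ABSENT = "absent"


@dataclass(frozen=True)
class StrictFilter:
    """Filter for reporting *novel* (not clinician-diagnosed) phenotypes.

    Only associations with HyI above threshold, full penetrance and a
    fully covered locus are confident enough to suggest clinical
    follow-up.
    """

    min_hyi: float = DEFAULT_THRESHOLD
    penetrance: float = 100.0
    locus_overlap_pct: float = 100.0

    def passes(self, row: "RankedPhenotype") -> bool:
        return (
            row.hyi > self.min_hyi
            and row.penetrance >= self.penetrance
            and row.locus_overlap_pct >= self.locus_overlap_pct
        )


@dataclass(frozen=True)
class RankedPhenotype:
    phenotype: str
    hyi: float
    penetrance: float
    pct_max: float
    locus_overlap_pct: float
    marker: Marker


@dataclass
class CaseReport:
    """Per-patient comparison of ranked vs clinician-observed phenotypes.

    ``matched`` (diagnosed and identified), ``novel`` (identified under
    the strict filter but not diagnosed) and ``missed`` (diagnosed but
    not identified) partition the union of diagnosed and reported terms.
    """

    patient_id: str
    ranked: list[tuple[LocusHit, list[RankedPhenotype]]]
    unmatched: list[GenomicInterval]
    observed: frozenset[str]
    matched: frozenset[str]
    novel: frozenset[str]
    missed: frozenset[str]
    detected_below_threshold: frozenset[str] = field(default_factory=frozenset)

    @property
    def identified(self) -> frozenset[str]:
        return frozenset(
            r.phenotype for _, rows in self.ranked for r in rows
        )


def rank_for_cnv(
    scores: Sequence[AssociationScore],
    loci: Sequence[Locus],
    query: CNVRecord,
    onto: Ontology,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[tuple[LocusHit, list[RankedPhenotype]]]:
    """Rank significant phenotypes for each locus a query CNV overlaps.

    For each overlapped locus, phenotypes with HyI >= threshold are
    sorted by HyI descending (ties broken by term id ascending); the
    "+"/"->" markers are computed over the reported set of that locus.
    A query overlapping no locus yields an empty list.
    """
    by_locus: dict[str, list[AssociationScore]] = {}
    for s in scores:
        by_locus.setdefault(s.locus_id, []).append(s)

    out: list[tuple[LocusHit, list[RankedPhenotype]]] = []
    for hit in map_query(loci, query.interval):
        rows = [s for s in by_locus.get(hit.locus.locus_id, ())
                if s.hyi >= threshold]
        rows.sort(key=lambda s: (-s.hyi, s.phenotype))
        reported = frozenset(s.phenotype for s in rows)
        specific, _parental = most_specific(onto, reported)
        ranked = [
            RankedPhenotype(
                phenotype=s.phenotype,
                hyi=s.hyi,
                penetrance=s.penetrance,
                pct_max=s.pct_max,
                locus_overlap_pct=hit.locus_overlap_pct,
                marker=Marker.SPECIFIC if s.phenotype in specific
                else Marker.PARENTAL,
            )
            for s in rows
        ]
        out.append((hit, ranked))
    return out


def compare_with_diagnosis(
    patient_id: str,
    ranked: list[tuple[LocusHit, list[RankedPhenotype]]],
    observed_direct: Iterable[str],
    onto: Ontology,
    query_intervals: Sequence[GenomicInterval] = (),
    strict: StrictFilter | None = None,
    below_threshold: Iterable[str] = (),
) -> CaseReport:
    """Build the per-case comparison sets.

    Observed terms are propagated through the ontology before
    comparison.  ``novel`` applies the strict filter: a phenotype with
    HyI > 2 but penetrance below 100% is not reported as novel.
    ``below_threshold`` optionally carries phenotypes detected at the
    query's loci with k >= 1 but HyI under threshold (for cohort grids).
    """
    strict = strict or StrictFilter()
    observed = propagate(onto, observed_direct).propagated
    identified = frozenset(r.phenotype for _, rows in ranked for r in rows)
    strict_identified = frozenset(
        r.phenotype for _, rows in ranked for r in rows if strict.passes(r)
    )
    unmatched: list[GenomicInterval] = []
    for q in query_intervals:
        hits = [h for h, _ in ranked if h.locus.interval.chrom == q.chrom]
        unmatched.extend(unmatched_region(hits, q))
    return CaseReport(
        patient_id=patient_id,
        ranked=ranked,
        unmatched=unmatched,
        observed=frozenset(observed),
        matched=frozenset(observed & identified),
        novel=frozenset(strict_identified - observed),
        missed=frozenset(observed - identified),
        detected_below_threshold=frozenset(below_threshold),
    )


def cohort_grid(
    cases: Sequence[CaseReport],
    phenotypes: Sequence[str],
) -> tuple[dict[tuple[str, str], GridTier], dict[str, tuple[int, int]]]:
    """Tier each (phenotype, patient) cell of a cohort grid.

    Tiers mirror the two-shade cohort table: a diagnosed phenotype found
    with significant HyI, found only below threshold, or not found; a
    phenotype predicted (strict novel filter) but never diagnosed; or
    absent.  Also returns per-phenotype counts
    (significant-hits, diagnosed) — the "9 associations found out of 10
    patients diagnosed" style summary.
    """
    grid: dict[tuple[str, str], GridTier] = {}
    counts: dict[str, tuple[int, int]] = {}
    for term in phenotypes:
        found = 0
        diagnosed = 0
        for case in cases:
            is_diag = term in case.observed
            if is_diag:
                diagnosed += 1
                if term in case.identified:
                    tier = GridTier.DIAGNOSED_AND_SIGNIFICANT
                    found += 1
                elif term in case.detected_below_threshold:
                    tier = GridTier.DIAGNOSED_AND_DETECTED_BELOW_THRESHOLD
                else:
                    tier = GridTier.DIAGNOSED_ONLY
            elif term in case.novel:
                tier = GridTier.PREDICTED_ONLY
            else:
                tier = GridTier.ABSENT
            grid[(term, case.patient_id)] = tier
        counts[term] = (found, diagnosed)
    return grid, counts


def summary_counters(
    cases: Sequence[CaseReport],
) -> dict[str, int]:
    """Cohort-level counters mirroring the diagnosed/identified comparison.

    Emitted in both countings — unique HPO terms across the cohort and
    patient-phenotype pairs — since either reading of "phenotypes
    diagnosed" is defensible.
    """
    def uniq(attr: str) -> int:
        out: set[str] = set()
        for c in cases:
            out |= getattr(c, attr)
        return len(out)

    def pairs(attr: str) -> int:
        return sum(len(getattr(c, attr)) for c in cases)

    return {
        "cases": len(cases),
        "cases_with_hits": sum(1 for c in cases if c.ranked),
        "diagnosed_terms_unique": uniq("observed"),
        "diagnosed_pairs": pairs("observed"),
        "matched_terms_unique": uniq("matched"),
        "matched_pairs": pairs("matched"),
        "novel_terms_unique": uniq("novel"),
        "novel_pairs": pairs("novel"),
        "missed_terms_unique": uniq("missed"),
        "missed_pairs": pairs("missed"),
    }
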