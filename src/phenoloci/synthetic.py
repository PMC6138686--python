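"""Reproducible synthetic cohorts with planted phenotype-locus associations.

Real rare-disease cohorts of this kind are access-controlled, so every
stage of the pipeline is exercised on generated data instead: a toy HPO
ontology (a random tree whose leaves are the assignable phenotypes),
patients each carrying 1-3 de novo CNVs and a handful of HPO terms, a
set of *planted* loci whose carriers receive a CNV containing the
planted interval plus a planted phenotype at a target penetrance, and
high-prevalence *background* phenotypes assigned independently to the
whole cohort.  A truth table records the planted pairs so recovery can
be scored.

Everything is driven by one seeded random stream; the same config and
seed reproduce the cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .association import AssociationScore, DEFAULT_THRESHOLD
from .cohort import (CNVRecord, Cohort, GenomicInterval, Inheritance,
                     VariantClass)
from .ontology import Ontology, parse_obo

ROOT_ID = "HP:0000001"


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class PlantedAssociation:
    """A locus-phenotype pair planted into the cohort."""

    interval: GenomicInterval
    phenotype: str
    penetrance: float      # target share of carriers expressing the phenotype
    carriers: int          # number of patients given a CNV over the interval


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults: 200 patients on two 10 Mb chromosomes, 1-3 de novo
    deletions each of 50-500 kb, two planted associations with 8 fully
    penetrant carriers each, three background phenotypes at 30%
    prevalence, and 2-10 noise terms per patient drawn from the toy
    ontology's leaves.
    """

    seed: int = 1
    n_patients: int = 200
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 10_000_000, "2": 10_000_000})
    cnv_per_patient: tuple[int, int] = (1, 3)
    cnv_length: tuple[int, int] = (50_000, 500_000)
    variant_class: VariantClass = VariantClass.DELETION
    planted: list[PlantedAssociation] | None = None
    background_prevalence: float = 0.3
    n_background: int = 3
    noise_terms_per_patient: tuple[int, int] = (2, 10)
    ontology_depth: int = 3
    ontology_branching: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.background_prevalence < 1.0):
            raise ConfigError("background prevalence must be in (0, 1)")
        if self.planted is not None:
            for p in self.planted:
                if not (0.0 < p.penetrance <= 1.0):
                    raise ConfigError("planted penetrance must be in (0, 1]")
                if p.carriers > self.n_patients:
                    raise ConfigError(
                        f"carrier count {p.carriers} exceeds cohort size "
                        f"{self.n_patients}")
                if p.interval.chrom not in self.chrom_lengths:
                    raise ConfigError(
                        f"planted chromosome {p.interval.chrom} unknown")


@dataclass
class TruthTable:
    """Ground truth for recovery scoring."""

    planted: list[PlantedAssociation]
    carriers: dict[str, frozenset[str]]   # phenotype -> carrier patient ids
    expressing: dict[str, frozenset[str]]  # phenotype -> carriers given the term
    background: list[str]                  # background phenotype ids


@dataclass
class RecoveryRow:
    phenotype: str
    locus_id: str | None
    hyi: float
    rank: int | None          # competition rank among the locus's phenotypes
    significant: bool


@dataclass
class RecoveryReport:
    rows: list[RecoveryRow]
    background_pairs: int
    background_significant: int

    @property
    def false_positive_rate(self) -> float:
        if self.background_pairs == 0:
            return 0.0
        return self.background_significant / self.background_pairs


def toy_ontology(depth: int = 3, branching: int = 3) -> Ontology:
    """Build a toy HPO-like tree of the given depth and branching.

    Term ids follow the HP:NNNNNNN pattern; the root mirrors the real
    ontology root id so default root exclusion applies.  Leaves of the
    deepest level are the assignable phenotypes.
    """
    counter = 2
    stanzas = [f"[Term]\nid: {ROOT_ID}\nname: All\n"]
    level = [ROOT_ID]
    for d in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                tid = f"HP:{counter:07d}"
                counter += 1
                stanzas.append(
                    f"[Term]\nid: {tid}\nname: term {tid[3:]}\n"
                    f"is_a: {parent} ! parent\n")
                nxt.append(tid)
        level = nxt
    header = "format-version: 1.2\nontology: toy-hpo\n\n"
    return parse_obo(header + "\n".join(stanzas))


def _leaves(onto: Ontology) -> list[str]:
    has_child = {p for ps in onto.is_a.values() for p in ps}
    return sorted(onto.terms - has_child)


def default_planted(onto: Ontology, chrom_lengths: dict[str, int],
                    carriers: int = 8,
                    penetrance: float = 1.0) -> list[PlantedAssociation]:
    """Two fully penetrant planted pairs, one per chromosome, on distinct leaves."""
    leaves = _leaves(onto)
    planted = []
    for i, chrom in enumerate(sorted(chrom_lengths)[:2]):
        L = chrom_lengths[chrom]
        start = L // 2
        planted.append(PlantedAssociation(
            interval=GenomicInterval(chrom, start, start + 100_000),
            phenotype=leaves[i],
            penetrance=penetrance,
            carriers=carriers,
        ))
    return planted


def generate(config: SimConfig) -> tuple[Cohort, Ontology, TruthTable]:
    """Generate a cohort, its toy ontology and the planted-pair truth table.

    Carriers of each planted pair receive one CNV containing the planted
    interval (random padding on both sides); exactly
    ``round(penetrance * carriers)`` of them receive the planted
    phenotype.  Background phenotypes are Bernoulli at their prevalence
    across the whole cohort; remaining CNVs and noise terms are placed
    uniformly.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    onto = toy_ontology(config.ontology_depth, config.ontology_branching)
    leaves = _leaves(onto)

    planted = config.planted
    if planted is None:
        planted = default_planted(onto, config.chrom_lengths)
    planted_terms = {p.phenotype for p in planted}
    for p in planted:
        if p.phenotype not in onto.terms:
            raise ConfigError(f"planted phenotype {p.phenotype} not in ontology")

    pool = [t for t in leaves if t not in planted_terms]
    background = pool[: config.n_background]
    noise_pool = pool[config.n_background:]
    if not noise_pool:
        raise ConfigError("ontology too small for noise terms")

    patients = [f"P{i + 1:04d}" for i in range(config.n_patients)]
    chroms = sorted(config.chrom_lengths)
    direct_terms: dict[str, set[str]] = {p: set() for p in patients}
    cnvs: list[CNVRecord] = []
    cnv_counter = 0

    def new_cnv(pid: str, interval: GenomicInterval) -> None:
        nonlocal cnv_counter
        cnv_counter += 1
        cnvs.append(CNVRecord(
            patient_id=pid, interval=interval,
            variant_class=config.variant_class,
            inheritance=Inheritance.DE_NOVO,
            cnv_id=f"cnv{cnv_counter:06d}",
        ))

    # planted carriers: CNV containing the interval + phenotype at penetrance
    truth_carriers: dict[str, frozenset[str]] = {}
    truth_expressing: dict[str, frozenset[str]] = {}
    for plant in planted:
        idx = rng.choice(config.n_patients, size=plant.carriers, replace=False)
        carrier_ids = [patients[i] for i in sorted(idx)]
        L = config.chrom_lengths[plant.interval.chrom]
        for pid in carrier_ids:
            pad_left = int(rng.integers(0, min(plant.interval.start, 200_000) + 1))
            pad_right = int(rng.integers(
                0, min(L - plant.interval.end, 200_000) + 1))
            new_cnv(pid, GenomicInterval(
                plant.interval.chrom,
                plant.interval.start - pad_left,
                plant.interval.end + pad_right,
            ))
        # who expresses is random, but the count is forced
        n_express = round(plant.penetrance * plant.carriers)
        express = [carrier_ids[i] for i in sorted(
            rng.choice(plant.carriers, size=n_express, replace=False))]
        for pid in express:
            direct_terms[pid].add(plant.phenotype)
        truth_carriers[plant.phenotype] = frozenset(carrier_ids)
        truth_expressing[plant.phenotype] = frozenset(express)

    # background phenotypes: independent Bernoulli at the prevalence
    for term in background:
        mask = rng.random(config.n_patients) < config.background_prevalence
        for pid, hit in zip(patients, mask):
            if hit:
                direct_terms[pid].add(term)

    # noise terms and remaining random CNVs
    lo_t, hi_t = config.noise_terms_per_patient
    lo_c, hi_c = config.cnv_per_patient
    lo_l, hi_l = config.cnv_length
    carrier_all = {pid for s in truth_carriers.values() for pid in s}
    for pid in patients:
        n_noise = int(rng.integers(lo_t, hi_t + 1))
        for i in rng.choice(len(noise_pool), size=min(n_noise, len(noise_pool)),
                            replace=False):
            direct_terms[pid].add(noise_pool[int(i)])
        n_cnv = int(rng.integers(lo_c, hi_c + 1))
        if pid in carrier_all:
            n_cnv = max(0, n_cnv - 1)  # the planted CNV counts toward the budget
        for _ in range(n_cnv):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = config.chrom_lengths[chrom]
            length = int(rng.integers(lo_l, hi_l + 1))
            start = int(rng.integers(0, L - length))
            new_cnv(pid, GenomicInterval(chrom, start, start + length))

    from .ontology import propagate
    annotations = {
        pid: propagate(onto, terms)
        for pid, terms in direct_terms.items() if terms
    }
    cohort = Cohort(cnvs=cnvs, annotations=annotations)
    truth = TruthTable(
        planted=list(planted),
        carriers=truth_carriers,
        expressing=truth_expressing,
        background=list(background),
    )
    return cohort, onto, truth


def _locus_interval(locus_id: str) -> GenomicInterval:
    chrom, span = locus_id.rsplit(":", 1)
    start, end = span.split("-")
    return GenomicInterval(chrom, int(start), int(end))


def recovery_report(
    scores: Sequence[AssociationScore],
    truth: TruthTable,
    threshold: float = DEFAULT_THRESHOLD,
) -> RecoveryReport:
    """Score recovery of planted pairs and the background false-positive rate.

    For each planted pair the best-scoring locus overlapping the planted
    interval is taken; the rank is the competition rank (1 + number of
    phenotypes with strictly greater HyI) among that locus's scored
    phenotypes.  Background pairs are all scored pairs whose phenotype is
    a background phenotype; the count significant at the threshold is the
    false-positive tally.
    """
    by_locus: dict[str, list[AssociationScore]] = {}
    for s in scores:
        by_locus.setdefault(s.locus_id, []).append(s)

    rows: list[RecoveryRow] = []
    for plant in truth.planted:
        best: AssociationScore | None = None
        for lid, locus_scores in by_locus.items():
            if _locus_interval(lid).overlap_bp(plant.interval) < 1:
                continue
            for s in locus_scores:
                if s.phenotype == plant.phenotype:
                    if best is None or s.hyi > best.hyi:
                        best = s
        if best is None:
            rows.append(RecoveryRow(plant.phenotype, None, 0.0, None, False))
            continue
        peers = by_locus[best.locus_id]
        rank = 1 + sum(1 for s in peers if s.hyi > best.hyi)
        rows.append(RecoveryRow(
            phenotype=plant.phenotype,
            locus_id=best.locus_id,
            hyi=best.hyi,
            rank=rank,
            significant=best.significant,
        ))

    bg = set(truth.background)
    bg_scores = [s for s in scores if s.phenotype in bg]
    return RecoveryReport(
        rows=rows,
        background_pairs=len(bg_scores),
        background_significant=sum(1 for s in bg_scores if s.significant),
    )


# --- file emission (formats consumed by the cohort/ontology readers) ---------

def write_cohort_files(
    cohort: Cohort, onto: Ontology, truth: TruthTable, outdir: str | Path
) -> None:
    """Emit cnvs.tsv (1-based inclusive), hpo.tsv, ontology.obo, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "cnvs.tsv", "w") as fh:
        fh.write("patient_id\tchrom\tstart\tend\tvariant_class\tinheritance\n")
        for c in cohort.cnvs:
            fh.write(f"{c.patient_id}\t{c.interval.chrom}\t"
                     f"{c.interval.start + 1}\t{c.interval.end}\t"
                     f"{c.variant_class.value}\t{c.inheritance.value}\n")
    with open(outdir / "hpo.tsv", "w") as fh:
        fh.write("patient_id\thpo_id\n")
        for pid in sorted(cohort.annotations):
            for t in sorted(cohort.annotations[pid].direct):
                fh.write(f"{pid}\t{t}\n")
    with open(outdir / "ontology.obo", "w") as fh:
        fh.write("format-version: 1.2\nontology: toy-hpo\n\n")
        for t in sorted(onto.terms):
            fh.write(f"[Term]\nid: {t}\nname: {onto.names.get(t, t)}\n")
            for p in sorted(onto.is_a.get(t, ())):
                fh.write(f"is_a: {p} ! {onto.names.get(p, p)}\n")
            fh.write("\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tphenotype\tpenetrance\tcarriers\n")
        for p in truth.planted:
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t"
                     f"{p.interval.end}\t{p.phenotype}\t{p.penetrance}\t"
                     f"{p.carriers}\n")
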