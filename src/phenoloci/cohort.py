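"""Patient CNV and phenotype-annotation tables.

Reads DECIPHER-style TSVs of patient copy-number variants and of
patient-HPO annotations, normalizes coordinates to 0-based half-open,
and applies the de novo / variant-class filters that define which records
enter each subnetwork.  Coordinates are carried as opaque positions on
named chromosomes; no sequence is ever read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, TextIO

import pandas as pd

from .ontology import Ontology, TermSet, propagate

logger = logging.getLogger(__name__)

HPO_ID_RE = re.compile(r"^HP:\d{7}$")

_CLASS_TOKENS = {
    "del": "deletion", "deletion": "deletion", "loss": "deletion",
    "dup": "duplication", "duplication": "duplication", "gain": "duplication",
}
_INHERITANCE_TOKENS = {
    "de_novo": "de_novo", "de novo": "de_novo", "denovo": "de_novo",
    "inherited": "inherited", "maternal": "inherited", "paternal": "inherited",
    "unknown": "unknown",
}


class VariantClass(str, Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


class Inheritance(str, Enum):
    DE_NOVO = "de_novo"
    INHERITED = "inherited"
    UNKNOWN = "unknown"


class CoordinateDialect(str, Enum):
    """How input start/end columns are interpreted.

    DECIPHER-style tables are 1-based inclusive; internally everything is
    0-based half-open so interval arithmetic is exact.
    """

    ONE_BASED_INCLUSIVE = "one_based_inclusive"
    ZERO_BASED_HALF_OPEN = "zero_based_half_open"


class CohortError(ValueError):
    """Malformed row in a cohort input table."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CNVRecord:
    """One patient structural variant."""

    patient_id: str
    interval: GenomicInterval
    variant_class: VariantClass
    inheritance: Inheritance
    cnv_id: str


@dataclass
class Cohort:
    """CNV records plus per-patient propagated phenotype annotations."""

    cnvs: list[CNVRecord]
    annotations: dict[str, TermSet]

    @property
    def patient_ids(self) -> frozenset[str]:
        return frozenset(c.patient_id for c in self.cnvs) | frozenset(
            self.annotations
        )


def _norm_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_cnvs(
    stream: TextIO | str,
    coordinate_dialect: CoordinateDialect | str = CoordinateDialect.ONE_BASED_INCLUSIVE,
) -> list[CNVRecord]:
    """Read a CNV TSV into normalized records.

    Expects a header with columns ``patient_id, chrom, start, end,
    variant_class, inheritance``; ``#``-prefixed lines are comments.
    Coordinates are converted from the given dialect to 0-based half-open.
    Each record receives a generated ``cnv_id`` unique within the file.

    Raises
    ------
    CohortError
        On a non-integer coordinate, unknown variant-class or inheritance
        token, or an empty interval, naming the offending row.
    """
    dialect = CoordinateDialect(coordinate_dialect)
    df = pd.read_csv(stream, sep="\t", comment="#", dtype=str)
    required = {"patient_id", "chrom", "start", "end", "variant_class", "inheritance"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"missing columns: {sorted(missing)}")

    records: list[CNVRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise CohortError(f"row {i}: non-integer coordinate "
                              f"({row.start!r}, {row.end!r})") from None
        if dialect is CoordinateDialect.ONE_BASED_INCLUSIVE:
            start -= 1
        if start >= end:
            raise CohortError(f"row {i}: start >= end after normalization "
                              f"({start} >= {end})")
        vc = _CLASS_TOKENS.get(str(row.variant_class).strip().lower())
        if vc is None:
            raise CohortError(f"row {i}: unknown variant_class "
                              f"{row.variant_class!r}")
        inh = _INHERITANCE_TOKENS.get(str(row.inheritance).strip().lower())
        if inh is None:
            raise CohortError(f"row {i}: unknown inheritance {row.inheritance!r}")
        records.append(CNVRecord(
            patient_id=str(row.patient_id),
            interval=GenomicInterval(_norm_chrom(row.chrom), start, end),
            variant_class=VariantClass(vc),
            inheritance=Inheritance(inh),
            cnv_id=f"cnv{i:06d}",
        ))
    return records


def write_cnvs(records: Iterable[CNVRecord], stream: TextIO) -> None:
    """Write records as a 0-based half-open TSV (round-trips with read_cnvs)."""
    stream.write("patient_id\tchrom\tstart\tend\tvariant_class\tinheritance\n")
    for r in records:
        stream.write(
            f"{r.patient_id}\t{r.interval.chrom}\t{r.interval.start}\t"
            f"{r.interval.end}\t{r.variant_class.value}\t{r.inheritance.value}\n"
        )


def filter_for_network(
    cnvs: Iterable[CNVRecord],
    variant_class: VariantClass | str,
    de_novo_only: bool = True,
) -> list[CNVRecord]:
    """Keep records of one variant class, optionally de novo only.

    De novo variants are the ones most likely to drive the pathological
    phenotype, so the reference subnetworks are built from them alone.
    Input order is preserved; an empty result is valid.
    """
    vc = VariantClass(variant_class)
    out = [
        c for c in cnvs
        if c.variant_class is vc
        and (not de_novo_only or c.inheritance is Inheritance.DE_NOVO)
    ]
    if not out:
        logger.warning("filter_for_network: no %s records retained", vc.value)
    return out


def read_patient_hpo(
    stream: TextIO | str, onto: Ontology
) -> dict[str, TermSet]:
    """Read patient-HPO rows and propagate each patient's terms.

    Expects columns ``patient_id, hpo_id``.  Duplicate rows deduplicate;
    well-formed but unknown HPO ids are logged and dropped (the patient
    keeps their remaining terms); a malformed id is a row error.
    """
    df = pd.read_csv(stream, sep="\t", comment="#", dtype=str)
    missing = {"patient_id", "hpo_id"} - set(df.columns)
    if missing:
        raise CohortError(f"missing columns: {sorted(missing)}")

    direct: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        hpo = str(row.hpo_id).strip()
        if not HPO_ID_RE.match(hpo):
            raise CohortError(f"row {i}: malformed HPO id {hpo!r}")
        if hpo not in onto.terms and hpo not in onto.obsolete:
            logger.warning("row %d: unknown HPO id %s dropped", i, hpo)
            continue
        direct.setdefault(str(row.patient_id), set()).add(hpo)
    return {pid: propagate(onto, terms) for pid, terms in direct.items()}
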