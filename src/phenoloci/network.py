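"""Tripartite phenotype-patient-locus network assembly.

One network per variant class: a phenotype layer (propagated HPO terms),
a patient layer, and a locus layer (SORs), with edges only between
adjacent layers through patients.  The population universe N is the set
of patients carrying at least one de novo CNV of the class — the
neighborhoods that the hypergeometric scoring draws on are defined
inside one subnetwork.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .cohort import CNVRecord, GenomicInterval, VariantClass
from .loci import Locus, segment_sors, write_bed
from .ontology import TermSet


@dataclass
class NetworkStats:
    patients: int
    loci: int
    phenotypes: int
    pheno_edges: int
    locus_edges: int


@dataclass
class TripartiteNetwork:
    """Patients linked to propagated phenotypes and to loci."""

    variant_class: VariantClass
    patients: frozenset[str]
    pheno_edges: dict[str, frozenset[str]]   # phenotype -> patients
    locus_edges: dict[str, frozenset[str]]   # locus_id -> patients
    loci: dict[str, Locus]
    phenotype_names: dict[str, str] = field(default_factory=dict)

    @property
    def n_population(self) -> int:
        return len(self.patients)


def build(
    cnvs: Sequence[CNVRecord],
    annotations: Mapping[str, TermSet],
    variant_class: VariantClass | str,
    phenotype_names: Mapping[str, str] | None = None,
) -> TripartiteNetwork:
    """Assemble the tripartite network for one variant class.

    ``cnvs`` must already be filtered to the class (and normally to de
    novo).  Patients are everyone with a CNV in the input; a patient with
    annotations but no CNV of this class is excluded entirely, and one
    with a CNV but no annotations appears in no phenotype edge.
    Phenotypes or loci left without patients are absent from the maps.

    Raises
    ------
    ValueError
        If ``cnvs`` is empty (no loci can be defined) or contains a
        record of another class.
    """
    vc = VariantClass(variant_class)
    if not cnvs:
        raise ValueError("cannot build a network without CNVs")
    for c in cnvs:
        if c.variant_class is not vc:
            raise ValueError(
                f"CNV {c.cnv_id} has class {c.variant_class.value}, "
                f"expected {vc.value}"
            )
    patients = frozenset(c.patient_id for c in cnvs)

    pheno_edges: dict[str, set[str]] = {}
    for pid, ts in annotations.items():
        if pid not in patients:
            continue
        for term in ts.propagated:
            pheno_edges.setdefault(term, set()).add(pid)

    loci_list = segment_sors(list(cnvs))
    loci = {l.locus_id: l for l in loci_list}
    locus_edges = {l.locus_id: l.patient_ids for l in loci_list}

    return TripartiteNetwork(
        variant_class=vc,
        patients=patients,
        pheno_edges={t: frozenset(s) for t, s in pheno_edges.items()},
        locus_edges=locus_edges,
        loci=loci,
        phenotype_names=dict(phenotype_names or {}),
    )


def stats(net: TripartiteNetwork) -> NetworkStats:
    """Count nodes and unique layer-to-layer edges for build logs."""
    return NetworkStats(
        patients=len(net.patients),
        loci=len(net.loci),
        phenotypes=len(net.pheno_edges),
        pheno_edges=sum(len(s) for s in net.pheno_edges.values()),
        locus_edges=sum(len(s) for s in net.locus_edges.values()),
    )


# --- serialization -----------------------------------------------------------

def save(net: TripartiteNetwork, outdir: str | Path, version: str = "") -> None:
    """Serialize the network to a directory of TSVs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "patients.tsv", "w") as fh:
        fh.write("patient_id\n")
        for p in sorted(net.patients):
            fh.write(p + "\n")
    with open(outdir / "pheno_edges.tsv", "w") as fh:
        fh.write("phenotype\tpatient_id\tphenotype_name\n")
        for t in sorted(net.pheno_edges):
            name = net.phenotype_names.get(t, "")
            for p in sorted(net.pheno_edges[t]):
                fh.write(f"{t}\t{p}\t{name}\n")
    with open(outdir / "locus_edges.tsv", "w") as fh:
        fh.write("locus_id\tpatient_id\n")
        for lid in sorted(net.locus_edges):
            for p in sorted(net.locus_edges[lid]):
                fh.write(f"{lid}\t{p}\n")
    with open(outdir / "loci.bed", "w") as fh:
        write_bed(
            sorted(net.loci.values(),
                   key=lambda l: (l.interval.chrom, l.interval.start)),
            fh,
        )
    with open(outdir / "loci_cnvs.tsv", "w") as fh:
        fh.write("locus_id\tcnv_id\n")
        for lid in sorted(net.loci):
            for c in sorted(net.loci[lid].cnv_ids):
                fh.write(f"{lid}\t{c}\n")
    digests = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(outdir.glob("*.tsv")) + [outdir / "loci.bed"]
    }
    manifest = {
        "variant_class": net.variant_class.value,
        "version": version,
        "digests": digests,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load(indir: str | Path) -> TripartiteNetwork:
    """Reload a serialized network."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    vc = VariantClass(manifest["variant_class"])

    patients = frozenset(
        line.strip()
        for line in (indir / "patients.tsv").read_text().splitlines()[1:]
        if line.strip()
    )
    pheno_edges: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for line in (indir / "pheno_edges.tsv").read_text().splitlines()[1:]:
        t, p, name = line.split("\t")
        pheno_edges.setdefault(t, set()).add(p)
        if name:
            names[t] = name
    locus_edges: dict[str, set[str]] = {}
    for line in (indir / "locus_edges.tsv").read_text().splitlines()[1:]:
        lid, p = line.split("\t")
        locus_edges.setdefault(lid, set()).add(p)
    locus_cnvs: dict[str, set[str]] = {}
    for line in (indir / "loci_cnvs.tsv").read_text().splitlines()[1:]:
        lid, c = line.split("\t")
        locus_cnvs.setdefault(lid, set()).add(c)
    loci: dict[str, Locus] = {}
    for line in (indir / "loci.bed").read_text().splitlines():
        chrom, start, end, lid, _, _ = line.split("\t")
        loci[lid] = Locus(
            locus_id=lid,
            interval=GenomicInterval(chrom, int(start), int(end)),
            cnv_ids=frozenset(locus_cnvs.get(lid, ())),
            patient_ids=frozenset(locus_edges.get(lid, ())),
            variant_class=vc,
        )
    return TripartiteNetwork(
        variant_class=vc,
        patients=patients,
        pheno_edges={t: frozenset(s) for t, s in pheno_edges.items()},
        locus_edges={l: frozenset(s) for l, s in locus_edges.items()},
        loci=loci,
        phenotype_names=names,
    )
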