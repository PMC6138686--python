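import io

import pytest

from phenoloci import (
    CNVRecord, CoordinateDialect, GenomicInterval, Inheritance, VariantClass,
    parse_obo, read_cnvs,
)

# Small ontology: root -> organ -> {ear -> low-set ears, heart}, a diamond
# child under ear and heart, and one obsolete term replaced by heart.
TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000002
name: organ abnormality
is_a: HP:0000001 ! All

[Term]
id: HP:0000003
name: abnormality of the ear
is_a: HP:0000002 ! organ abnormality

[Term]
id: HP:0000004
name: low-set ears
is_a: HP:0000003 ! abnormality of the ear

[Term]
id: HP:0000005
name: heart abnormality
is_a: HP:0000002

[Term]
id: HP:0000006
name: diamond child
is_a: HP:0000003
is_a: HP:0000005

[Term]
id: HP:0000007
name: obsolete thing
is_obsolete: true
replaced_by: HP:0000005
"""


@pytest.fixture(scope="session")
def toy_onto():
    return parse_obo(TOY_OBO)


def make_cnv(pid, chrom, start, end, vclass=VariantClass.DELETION,
             inh=Inheritance.DE_NOVO, cnv_id=None):
    return CNVRecord(
        patient_id=pid,
        interval=GenomicInterval(chrom, start, end),
        variant_class=vclass,
        inheritance=inh,
        cnv_id=cnv_id or f"{pid}-{chrom}-{start}-{end}",
    )


@pytest.fixture
def cnv_tsv():
    text = (
        "patient_id\tchrom\tstart\tend\tvariant_class\tinheritance\n"
        "P1\t17\t34817222\t34817420\tdel\tde_novo\n"
        "P2\tchr17\t34817000\t34817300\tDEL\tde novo\n"
        "P3\t2\t100\t500\tloss\tinherited\n"
        "P4\tX\t1000\t2000\tdup\tde_novo\n"
    )
    return io.StringIO(text)
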