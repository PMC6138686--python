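# phenoloci

Tripartite phenotype–patient–CNV networks for rare genomic disorders.

Many rare syndromes are caused by copy-number variants (CNVs) — deletions or
duplications of genomic segments — but with so few patients per variant it is
hard to establish which phenotypes a mutated region actually drives.
`phenoloci` pools the genotype and phenotype records of a whole cohort into a
three-layer network and scores every phenotype–locus pair statistically, so
that a clinician facing a *new* patient with an uncharacterized CNV can be
shown a ranked list of phenotypes previously associated with the overlapped
regions. It is aimed at clinical geneticists and methodologists working with
DECIPHER-style cohorts of patients with de novo CNVs annotated in the Human
Phenotype Ontology (HPO).

## Method

1. **Loci (SORs).** Patient CNVs of one class (deletions or duplications,
   de novo only) are segmented at their breakpoints into *small overlapping
   regions*: maximal genomic segments covered by a constant set of CNVs.
   Loci partition the CNV-covered genome; adjacent loci differ in their
   supporting CNVs.
2. **Phenotype propagation.** Each patient's HPO terms are propagated up the
   ontology: an annotation implies every ancestral term (the root is
   excluded).
3. **Tripartite network.** Phenotype nodes and locus nodes are linked through
   the patient layer, one network per variant class.
4. **Hypergeometric Index.** For a phenotype *A* and a locus *B*, with
   *N* patients in the subnetwork, *K* = deg(*A*), *n* = deg(*B*) and
   *k* shared patients,

   HyI = −log₁₀ P(X ≥ k),  X ~ Hypergeometric(N, K, n).

   HyI ≥ 2.0 (p ≤ 0.01) is called significant. A prevalent phenotype (large
   *K*) scores low everywhere; a phenotype concentrated in one locus's
   patients scores high — the index rewards specificity.
5. **Auxiliary parameters.** *Penetrance* = 100·k/n, the share of patients at
   the locus expressing the phenotype; *% max* = a pair's HyI relative to the
   phenotype's best locus; *locus overlap* = the percentage of a reference
   locus covered by the query CNV.
6. **Query ranking.** A novel case's CNV is mapped onto the loci by overlap;
   for each hit the significant phenotypes are ranked by HyI, marked "+"
   (most specific reported term) or "->" (parental term), and compared with
   the clinician's observed phenotypes.

Because real cohorts of this kind are access-controlled, the package includes
a first-class synthetic-cohort generator with planted phenotype–locus
associations, used by the test suite and the acceptance script.

## Worked example

Generate a 200-patient synthetic cohort (two planted associations, eight
fully penetrant carriers each, three 30%-prevalence background phenotypes),
build and score the deletion subnetwork, and query a CNV spanning the first
planted interval:

```sh
phenoloci simulate --seed 1 --n-patients 200 --out sim
# patients  200
# cnvs      400
# planted   2

phenoloci score --cnvs sim/cnvs.tsv --hpo sim/hpo.tsv \
    --obo sim/ontology.obo --out assoc.tsv
# pairs_scored  25913
# significant   148

phenoloci query --cnvs sim/cnvs.tsv --hpo sim/hpo.tsv \
    --obo sim/ontology.obo --query query.tsv --out report.tsv
# queries      1
# ranked_rows  17
```

`report.tsv` begins:

```
patient_id  cnv                locus_id           locus_overlap_pct  marker  phenotype_id  hyi      penetrance  pct_max
CASE1       1:5000000-5100000  1:4994489-5028712  83.9               +       HP:0000014    10.2636  57.1        89.1
CASE1       1:5000000-5100000  1:4994489-5028712  83.9               ->      HP:0000005    2.7061   78.6        89.3
CASE1       1:5000000-5100000  1:5028712-5046624  100.0              +       HP:0000014    9.9326   53.3        86.2
```

The planted phenotype HP:0000014 tops every overlapped locus with HyI ≈ 10
(p ≈ 10⁻¹⁰): its eight carriers all share the region. HP:0000005, its
ontology parent, appears below it marked "->"; penetrance is diluted below
100% where random CNVs from non-expressing patients also cover the locus.
The second locus is fully contained in the query (locus overlap 100%).

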