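# Methods

## Model

`phenoloci` treats a cohort of rare-disease patients as a tripartite graph:
phenotype nodes (HPO terms), patient nodes, and locus nodes, with edges only
between adjacent layers through patients. Deletions and duplications form
separate subnetworks, since the two variant classes of the same region can
have opposite phenotypic effects; only de novo CNVs enter a network, as they
are the variants most likely to drive the pathological phenotype.

**Loci.** A locus is a maximal genomic segment covered by a constant set of
CNVs ("small overlapping region", SOR). We formalize this as breakpoint
segmentation: collect all CNV start/end positions on a chromosome, form the
elementary intervals between consecutive breakpoints, attach the covering
CNV set, drop uncovered gaps, and merge adjacent segments with identical CNV
sets. Two properties follow and are enforced by tests: the loci partition
exactly the CNV-covered genome (bp-exact conservation), and every CNV is
exactly tiled by the loci it supports. Whether one merges equal-coverage
neighbours or keeps raw elementary segments does not change any
patient–locus edge set, hence no association score; we merge, which makes
locus ids stable and reports shorter.

**Phenotype propagation.** An HPO annotation implies all ancestral terms, so
each patient's direct terms are closed upward over `is_a` edges. The
ontology root is excluded (it would connect every patient to every
phenotype; the excluded root list is configurable). HPO is a DAG, not a
tree: multi-parent diamonds are closed over set union, so each ancestor is
counted once. Only `is_a` relations are interpreted; obsolete terms are
mapped through `replaced_by` when present, otherwise dropped with a warning.

**Association score.** For phenotype A and locus B in one subnetwork with
N patients, K annotated with A, n at B and k shared,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),   HyI = -log10(p).

The tail is inclusive ("equal or greater"), computed via
`scipy.stats.hypergeom.logsf` in log space; HyI is capped at 300 to absorb
underflow, and the cap is recorded here as output metadata. Significance is
HyI >= 2.0, i.e. p <= 0.01; the flag is computed directly from
`p <= 10^(-threshold)` so the flip is exact at the boundary (in IEEE
doubles, `-log10(0.01) == 2.0` also holds exactly). Pairs with k = 0 are not
scored — they cannot be significant — unless explicitly requested. No
multiple-testing correction gates the reports; a Benjamini–Hochberg column
is emitted as supplementary output only, because the method's operating
point is the raw HyI >= 2 rule and its calibration is itself measured (see
below).

**Auxiliary parameters.** Penetrance = 100·k/n (share of the locus's
patients expressing the phenotype). % max = 100·HyI/max-HyI of that
phenotype across the loci of the same subnetwork; tied maxima all receive
100. Locus overlap = 100·(overlap bp)/(locus length): the denominator is the
*locus* length, so 100% means the query CNV contains the whole locus. A
large query CNV therefore shows 100% against each small locus it swallows,
which is the reading consistent with per-patient report tables; the
alternative (query-length denominator) would make the same number depend on
the query size.

**Query ranking.** Queries are scored against the pre-built reference
network and never added to it. Per overlapped locus, phenotypes with
HyI >= threshold are sorted by HyI descending, ties broken by term id for
determinism. The "+"/"->" markers partition the *reported* set of each locus
by `most_specific`: a term is parental exactly when another reported term
descends from it. The strict filter for reporting *novel* (not diagnosed)
phenotypes requires HyI > 2, penetrance 100% and locus overlap 100%;
anything weaker is shown but not flagged as a suggested follow-up. Cohort
grids tier each (phenotype, patient) cell as diagnosed-and-significant,
diagnosed-but-below-threshold, diagnosed-only, predicted-only or absent.

## Synthetic cohorts

Real DECIPHER-scale data is access-controlled, so the generator emulates its
structure: N patients (default 200) each carry 1–3 de novo CNVs (50–500 kb,
uniform on two 10 Mb toy chromosomes) and a handful of HPO terms from a
random toy ontology (depth 3, branching 3; assignable phenotypes are
leaves). Two associations are planted by default: 8 carriers each receive a
CNV containing a 100 kb interval plus the planted leaf phenotype at
penetrance 1.0 (exactly `round(penetrance × carriers)` carriers express it).
Three background phenotypes are assigned cohort-wide at 30% prevalence, and
each patient draws 2–10 noise leaves, so planted ancestors acquire extra
patients through sibling leaves and rank below their planted child. All
randomness comes from one seeded NumPy generator; a config and seed
reproduce the cohort byte-for-byte.

What the generator does *not* emulate: realistic human CNV length and
recurrence distributions, chromosome-specific breakpoint hotspots, hg19
coordinates, correlated phenotype co-occurrence, and annotation noise
(wrong or missing clinical terms). Passing recovery tests therefore show
that the statistics and plumbing behave as specified under known ground
truth — not that the method's clinical sensitivity on real cohorts matches
any particular figure.

## Numerical and design choices

- Coordinates are 0-based half-open internally; the default input dialect is
  1-based inclusive (the convention of DECIPHER-style tables). Half-open
  arithmetic makes segmentation exact with no ±1 bookkeeping.
- Chromosome names are opaque labels ("chr" prefixes stripped); sex
  chromosomes get no special treatment.
- The population universe N of a subnetwork is the set of patients carrying
  at least one de novo CNV of that class — not all annotated patients —
  because the score's neighborhoods are defined inside one subnetwork.
  Patients with CNVs but no annotations stay in N; annotated patients
  without a CNV of the class are excluded.
- A patient with several CNVs over one locus contributes a single
  patient–locus edge (set semantics).
- `hypergeom_tail` is checked against an exact rational-arithmetic
  enumeration (`math.comb` + `Fraction`) over every admissible
  (N ≤ 30, K, n, k) tuple; observed agreement is at machine precision
  (≤ 1e-12 relative error required).
- Recovery rank is the competition rank: 1 + the number of phenotypes at the
  locus with strictly greater HyI, so exact ties (e.g. an ancestor with an
  identical patient set) do not penalize the planted term.
- Degenerate inputs: an empty CNV list yields no loci and network build
  fails loudly; a patient with no annotations simply has no phenotype edges;
  an empty direct term set propagates to an empty set.

## Problem sizes

The test suite and acceptance script run the full pipeline on 200-patient
cohorts (~400 CNVs, ~800 loci, ~26k scored pairs per cohort; seeds 1–5),
exhaustive hypergeometric grids to N = 30 (~87k tuples), and 500 random
20-CNV cohorts for segmentation checks. These sizes were chosen so the
whole suite completes in a couple of minutes while every claim is exercised
at full fidelity; nothing in the method is specific to this scale, and the
scoring loop is linear in the number of connected phenotype–locus pairs.

## Known limitations

- Associations are correlational; confounding by cohort composition or
  ascertainment is not modeled.
- Propagated ancestors share their descendants' patients, so parental terms
  ride along with significant children (reported explicitly via "->").
- The raw HyI >= 2 rule controls the per-pair error rate, not the
  family-wise rate across hundreds of thousands of pairs; the supplementary
  BH column exists for users who want the stricter view.
- Loci carry no gene annotation; interpreting *why* a region associates
  with a phenotype is out of scope.
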