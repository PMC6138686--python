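"""Synthetic cohort generator: determinism, planted structure, recovery."""

import pytest

from phenoloci import (GenomicInterval, PlantedAssociation, SimConfig,
                       build, filter_for_network, generate, recovery_report,
                       score_all, toy_ontology)
from phenoloci.synthetic import ConfigError, _leaves


def small_config(seed=1, **kw):
    defaults = dict(
        seed=seed, n_patients=60,
        chrom_lengths={"1": 2_000_000},
        cnv_per_patient=(1, 2), cnv_length=(20_000, 100_000),
        n_background=2, noise_terms_per_patient=(2, 5),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_determinism_same_seed_same_cohort():
    a_cohort, a_onto, a_truth = generate(small_config(seed=7))
    b_cohort, b_onto, b_truth = generate(small_config(seed=7))
    assert a_cohort.cnvs == b_cohort.cnvs
    assert a_cohort.annotations == b_cohort.annotations
    assert a_truth.carriers == b_truth.carriers
    c_cohort, _, _ = generate(small_config(seed=8))
    assert c_cohort.cnvs != a_cohort.cnvs


def test_planted_carriers_have_covering_cnv_and_phenotype():
    cohort, onto, truth = generate(small_config())
    for plant in truth.planted:
        carriers = truth.carriers[plant.phenotype]
        assert len(carriers) == plant.carriers
        for pid in carriers:
            assert any(
                c.patient_id == pid
                and c.interval.chrom == plant.interval.chrom
                and c.interval.start <= plant.interval.start
                and c.interval.end >= plant.interval.end
                for c in cohort.cnvs)
        # full penetrance: every carrier expresses the phenotype
        expressing = truth.expressing[plant.phenotype]
        assert expressing == carriers
        for pid in expressing:
            assert plant.phenotype in cohort.annotations[pid].direct


def test_partial_penetrance_rounds_carrier_count():
    onto = toy_ontology()
    leaf = _leaves(onto)[0]
    cfg = small_config(planted=[PlantedAssociation(
        GenomicInterval("1", 1_000_000, 1_100_000), leaf,
        penetrance=0.5, carriers=8)])
    cohort, _, truth = generate(cfg)
    assert len(truth.expressing[leaf]) == 4  # round(0.5 * 8)
    assert truth.expressing[leaf] <= truth.carriers[leaf]


def test_infeasible_configs_rejected():
    with pytest.raises(ConfigError):
        SimConfig(background_prevalence=1.5)
    with pytest.raises(ConfigError):
        small_config(planted=[PlantedAssociation(
            GenomicInterval("1", 0, 100), "HP:0000002",
            penetrance=1.0, carriers=999)])
    with pytest.raises(ConfigError):
        small_config(planted=[PlantedAssociation(
            GenomicInterval("1", 0, 100), "HP:0000002",
            penetrance=0.0, carriers=2)])


def test_recovery_report_on_small_cohort():
    cohort, onto, truth = generate(small_config(seed=3))
    cnvs = filter_for_network(cohort.cnvs, "deletion")
    net = build(cnvs, cohort.annotations, "deletion")
    scores = score_all(net)
    rep = recovery_report(scores, truth)
    assert len(rep.rows) == len(truth.planted)
    for row in rep.rows:
        assert row.locus_id is not None
        assert row.significant and row.rank == 1
    assert 0.0 <= rep.false_positive_rate <= 1.0


def test_ubiquitous_phenotype_never_significant():
    # a phenotype planted in every patient has K = N: certain event
    onto = toy_ontology()
    leaf = _leaves(onto)[0]
    n = 40
    cfg = small_config(
        n_patients=n,
        planted=[PlantedAssociation(
            GenomicInterval("1", 900_000, 1_000_000), leaf,
            penetrance=1.0, carriers=n)])
    cohort, _, truth = generate(cfg)
    # force the phenotype onto everyone
    from phenoloci import propagate
    ann = {pid: propagate(onto, set(ts.direct) | {leaf})
           for pid, ts in cohort.annotations.items()}
    net = build(filter_for_network(cohort.cnvs, "deletion"), ann, "deletion")
    for s in score_all(net):
        if s.phenotype == leaf:
            assert s.hyi == 0.0 and not s.significant


def test_empty_truth_table_recovery():
    cohort, onto, truth = generate(small_config(seed=2))
    net = build(filter_for_network(cohort.cnvs, "deletion"),
                cohort.annotations, "deletion")
    scores = score_all(net)
    from phenoloci import TruthTable
    empty = TruthTable(planted=[], carriers={}, expressing={},
                       background=truth.background)
    rep = recovery_report(scores, empty)
    assert rep.rows == []
    assert rep.background_pairs > 0


def test_prevalence_depresses_hyi_sign_test():
    """Raising a planted phenotype's background prevalence lowers its HyI.

    The specific-vs-prevalent contrast: the same locus association scores
    lower when the phenotype is common cohort-wide.  Checked as a sign
    test over 20 seeds.
    """
    onto = toy_ontology()
    leaf = _leaves(onto)[0]
    wins = 0
    for seed in range(1, 21):
        hyis = []
        for prevalence in (None, 0.5):
            cfg = small_config(
                seed=seed,
                planted=[PlantedAssociation(
                    GenomicInterval("1", 1_000_000, 1_100_000), leaf,
                    penetrance=1.0, carriers=6)])
            cohort, _, truth = generate(cfg)
            ann = cohort.annotations
            if prevalence is not None:
                import numpy as np
                from phenoloci import propagate
                rng = np.random.default_rng(seed + 1000)
                ann = dict(ann)
                for pid in sorted(ann):
                    if rng.random() < prevalence:
                        ann[pid] = propagate(
                            onto, set(ann[pid].direct) | {leaf})
            net = build(filter_for_network(cohort.cnvs, "deletion"),
                        ann, "deletion")
            rep = recovery_report(score_all(net), truth)
            hyis.append(rep.rows[0].hyi)
        if hyis[1] < hyis[0]:
            wins += 1
    assert wins >= 15  # clear majority under a one-sided sign test
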