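"""Simulator contracts: determinism, truth statistics, error model, fixture."""

import dataclasses
import gzip
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutprev.simulate import (ConfigurationError, SimulationConfig,
                              simulate_cohort, simulate_sample_reads,
                              uniform_error_matrix, write_fastq,
                              write_truth_and_fixture)
from conftest import barcoded


@pytest.mark.parametrize("field,value,message", [
    ("reads_per_molecule_mean", 0.0, "reads_per_molecule_mean"),
    ("clone_vaf_range", (0.0, 0.01), "clone_vaf_range"),
    ("clone_vaf_range", (0.5, 1.5), "clone_vaf_range"),
    ("eccl_rungs", (50, 500), "eccl_rungs"),
    ("eccl_rungs", (), "eccl_rungs"),
    ("n_subjects_case", -1, "n_subjects_case"),
    ("signature_weights", {"C>A": 0.5}, "signature_weights"),
])
def test_invalid_config_names_field(field, value, message):
    cfg = dataclasses.replace(SimulationConfig(), **{field: value})
    with pytest.raises(ConfigurationError, match=message):
        cfg.validate()


def test_error_matrix_rows_must_sum_to_one():
    bad = np.full((4, 4), 0.1)
    cfg = SimulationConfig(error_matrix=bad)
    with pytest.raises(ConfigurationError, match="error_matrix"):
        cfg.validate()


def test_zero_clone_means_give_zero_mutations(panel):
    cfg = SimulationConfig(seed=1, clone_mean_case=0.0,
                           clone_mean_control=0.0)
    cohort, truth = simulate_cohort(cfg, panel)
    assert all(not s.mutations for s in truth.subjects)
    assert (cohort.true_clone_count == 0).all()


def test_cohort_is_deterministic_given_seed(panel):
    a = simulate_cohort(SimulationConfig(seed=1), panel)
    b = simulate_cohort(SimulationConfig(seed=1), panel)
    pd.testing.assert_frame_equal(a[0], b[0])
    for sa, sb in zip(a[1].subjects, b[1].subjects):
        assert sa == sb


def test_fastq_bytes_identical_for_same_seed(panel, small_config, tmp_path):
    paths = []
    for name in ("a", "b"):
        _, truth = simulate_cohort(small_config, panel)
        subject = truth.subjects[0]
        p = barcoded(panel, [subject])
        blocks, _ = simulate_sample_reads(subject, p, small_config)
        out = tmp_path / f"{name}.fastq.gz"
        write_fastq(blocks, p, out)
        paths.append(out)
    assert gzip.open(paths[0]).read() == gzip.open(paths[1]).read()


def test_clone_count_means_match_configuration(panel):
    # group means mimic the cohort totals: 159/30 cases, 33/29 controls
    cfg = SimulationConfig(seed=3, n_subjects_case=30, n_subjects_control=29,
                           clone_mean_case=5.2, clone_mean_control=1.1)
    cohort, _ = simulate_cohort(cfg, panel)
    for group, mean in (("CA", 5.2), ("NC", 1.1)):
        counts = cohort[cohort.cancer_status == group].true_clone_count
        se = math.sqrt(mean / len(counts))  # Poisson SE of the mean
        assert abs(counts.mean() - mean) < 3 * se


def test_truth_mutations_respect_mask_and_vaf_range(panel):
    cfg = SimulationConfig(seed=4, n_subjects_case=20, n_subjects_control=0,
                           clone_mean_case=8.0)
    _, truth = simulate_cohort(cfg, panel)
    lo, hi = cfg.clone_vaf_range
    seen = 0
    for s in truth.subjects:
        keys = {(m.target, m.pos, m.alt) for m in s.mutations}
        assert len(keys) == len(s.mutations)  # clones are unique sites
        for m in s.mutations:
            amp = panel.amplicons[m.target]
            assert m.pos in set(amp.analyzable_positions.tolist())
            assert amp.sequence[m.pos] == m.ref
            assert lo <= m.vaf <= hi
            seen += 1
    assert seen > 50


def test_signature_classes_follow_weights(panel):
    cfg = SimulationConfig(seed=5, n_subjects_case=150, n_subjects_control=0,
                           clone_mean_case=8.0)
    _, truth = simulate_cohort(cfg, panel)
    observed = {c: 0 for c in cfg.signature_weights}
    for s in truth.subjects:
        for m in s.mutations:
            observed[m.sig_class] += 1
    n = sum(observed.values())
    assert n >= 1000
    classes = list(cfg.signature_weights)
    f_obs = [observed[c] for c in classes]
    f_exp = [cfg.signature_weights[c] * n for c in classes]
    _, p = stats.chisquare(f_obs, f_exp)
    assert p > 0.01


def test_noise_free_reads_match_their_templates(panel, small_config):
    cfg = dataclasses.replace(small_config, error_matrix=np.eye(4),
                              clone_mean_case=0.0, clone_mean_control=0.0,
                              n_subjects_case=1, n_subjects_control=0)
    _, truth = simulate_cohort(cfg, panel)
    subject = truth.subjects[0]
    blocks, _ = simulate_sample_reads(subject, barcoded(panel, [subject]),
                                      cfg)
    for block in blocks:
        assert block.err_read.size == 0
        amp = panel.amplicons[block.target]
        seq = "".join("ACGT"[i] for i in block.template)
        if block.origin_truth == "NT":
            assert seq == amp.sequence
        else:
            expected = (amp.eccl_sequence(block.rung_truth)
                        if block.rung_truth else amp.is_sequence)
            assert seq == expected
            diffs = {i for i, (a, b) in
                     enumerate(zip(seq, amp.sequence)) if a != b}
            assert set(amp.dinucleotide_positions) <= diffs


def test_read_totals_follow_truncated_poisson_duplication(panel,
                                                          small_config):
    _, truth = simulate_cohort(small_config, panel)
    subject = truth.subjects[0]
    blocks, _ = simulate_sample_reads(subject, barcoded(panel, [subject]),
                                      small_config)
    lam = small_config.reads_per_molecule_mean
    mean_z = lam / (1 - math.exp(-lam))
    var_z = (lam + lam ** 2) / (1 - math.exp(-lam)) - mean_z ** 2
    for block in blocks:
        assert block.n_reads >= block.n_molecules  # every molecule >=1 read
        se = math.sqrt(block.n_molecules * var_z)
        assert abs(block.n_reads - block.n_molecules * mean_z) < 4 * se + 10


def test_mutant_molecule_counts_are_binomial(panel):
    # one clone at VAF 0.005 among 50,000 NT molecules -> ~250 +/- 3 SE
    cfg = SimulationConfig(seed=11, n_subjects_case=1, n_subjects_control=0,
                           clone_mean_case=1.0, clone_vaf_range=(5e-3, 5e-3),
                           reads_per_molecule_mean=1.0)
    rng_trials = []
    _, truth = simulate_cohort(cfg, panel)
    subject = truth.subjects[0]
    while not subject.mutations:  # Poisson(1) may draw zero clones
        cfg = dataclasses.replace(cfg, seed=cfg.seed + 1)
        _, truth = simulate_cohort(cfg, panel)
        subject = truth.subjects[0]
    m = subject.mutations[0]
    p = barcoded(panel, [subject])
    for trial_seed in range(5):
        rng = np.random.default_rng(1000 + trial_seed)
        blocks, _ = simulate_sample_reads(subject, p, cfg, rng=rng)
        mut = [b for b in blocks if b.target == m.target
               and b.origin_truth == "NT"
               and b.template[m.pos] == "ACGT".index(m.alt)]
        assert len(mut) == 1
        rng_trials.append(mut[0].n_molecules)
    n, vaf = 50_000, m.vaf
    se = math.sqrt(n * vaf * (1 - vaf))
    for count in rng_trials:
        assert abs(count - n * vaf) < 4 * se


def test_eccl_observations_cover_every_rung(panel, small_config):
    _, truth = simulate_cohort(small_config, panel)
    subject = truth.subjects[0]
    _, eccl = simulate_sample_reads(subject, barcoded(panel, [subject]),
                                    small_config)
    assert sorted(o.rung for o in eccl) == [1, 2, 3, 4]
    nominals = [o.nominal_molecules for o in sorted(eccl,
                                                    key=lambda o: o.rung)]
    assert nominals == list(small_config.eccl_rungs)
    for o in eccl:
        assert o.reads >= o.nominal_molecules


def test_truth_mutation_outside_panel_rejected(panel, small_config):
    from mutprev.simulate import SubjectTruth, TruthMutation

    bad = SubjectTruth(
        subject_id="X", group="CA",
        mutations=[TruthMutation("TP53.5", 5, "A", "C", 0.005, "other")],
        nt_molecules={t: 100 for t in panel.amplicons},
        is_molecules={t: 100 for t in panel.amplicons if t != "SCGB1A1"},
        eccl_molecules={1: 100, 2: 10, 3: 5, 4: 2}, read_seed=1)
    with pytest.raises(ValueError, match="mask"):
        simulate_sample_reads(bad, barcoded(panel, [bad]), small_config)


def test_write_truth_and_fixture_outputs(panel, small_config, tmp_path):
    paths = write_truth_and_fixture(tmp_path / "out", small_config, panel)
    fixture = pd.read_csv(paths["cohort_fixture"],
                          dtype={"protocol_id": str})
    assert len(fixture) == 60
    assert (fixture.cancer_status == "CA").sum() == 30
    assert (fixture.cancer_status == "NC").sum() == 30
    assert (fixture.tp53_prevalence == "Not measured").sum() == 1
    # serialization identity round trip
    again = pd.read_csv(paths["cohort_fixture"], dtype={"protocol_id": str})
    pd.testing.assert_frame_equal(fixture, again)
    truth = pd.read_csv(paths["truth_mutations"], sep="\t")
    assert set(truth.columns) >= {"subject_id", "target", "pos", "vaf"}
    with gzip.open(paths["fastq"], "rt") as fh:
        first = fh.readline()
    assert first.startswith("@")
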