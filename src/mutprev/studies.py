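"""Simulation studies validating the pipeline's operating characteristics.

Each study generates synthetic cohorts at declared conditions, pushes every
sample through the full pipeline (simulate reads -> classify -> calibrate ->
down-sample -> call), and summarizes one operating characteristic:

* ``null_call_study`` - family-wise false-call control when NT and IS share
  the error process and no true mutations exist.
* ``detection_study`` - sensitivity to clones whose VAF is at least 10x the
  limit of blank, plus molecule-count calibration accuracy, at the assay's
  50,000-molecule scale.
* ``auc_recovery_study`` - whether a case-control cohort whose true
  clone-count separation corresponds to AUC 0.85 yields an estimated AUC
  whose 95% CI covers the truth.  This study runs at a reduced
  2,000-molecule library scale: clone VAFs are set high enough (>= 0.8%)
  that detection is effectively certain, so the statistical content is the
  sampling behavior of the AUC at n = 30 cases / 29 controls.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import biomarker, pipeline
from .panel import TargetPanel, make_barcodes, mock_panel
from .simulate import SimulationConfig, simulate_cohort

#: per-substitution technical error shared by NT and IS (study condition)
ERROR_RATE = 1e-4


def poisson_mann_whitney_auc(mean_case: float, mean_control: float,
                             kmax: int = 200) -> float:
    """True AUC (half-credit ties) between two Poisson count distributions."""
    k = np.arange(kmax)
    pa = stats.poisson.pmf(k, mean_case)
    pn = stats.poisson.pmf(k, mean_control)
    below = np.concatenate([[0.0], np.cumsum(pn)[:-1]])
    return float(np.sum(pa * (below + 0.5 * pn)))


#: clone-count means whose Poisson distributions separate with true AUC 0.850
AUC_STUDY_CLONE_MEANS = (3.3287, 33 / 29)


def _run_cohort(config: SimulationConfig, panel: TargetPanel | None = None,
                **sample_kwargs):
    if panel is None:
        panel = mock_panel()
    cohort, truth = simulate_cohort(config, panel)
    panel = panel.with_barcodes(make_barcodes(
        [s.subject_id for s in truth.subjects], seed=config.seed + 101))
    results = {s.subject_id: pipeline.run_sample(s, panel, config,
                                                 **sample_kwargs)
               for s in truth.subjects}
    return cohort, truth, results


def null_call_study(n_samples: int = 20, seed: int = 0) -> dict:
    """Zero-mutation cohort under the shared error process.

    With a valid blank and Bonferroni control at alpha = 0.05, at least 95%
    of samples should yield zero variant calls.
    """
    config = SimulationConfig(seed=seed, n_subjects_case=0,
                              n_subjects_control=n_samples,
                              clone_mean_control=0.0)
    _, truth, results = _run_cohort(config)
    calls = [len(results[s.subject_id].calls) for s in truth.subjects]
    return {"n_samples": n_samples,
            "calls_per_sample": calls,
            "clean_fraction": float(np.mean([c == 0 for c in calls]))}


def detection_study(n_samples: int = 100, seed: int = 0) -> dict:
    """Sensitivity at VAF >= 10x LOB and molecule-calibration accuracy.

    Simulates ``n_samples`` subjects at the assay scale (50,000 molecules
    per target) whose clones all lie at VAF >= 1e-3 = 10x the expected LOB.
    Reports pooled clone-level sensitivity and the relative bias of the
    per-target NT molecule estimates against the true 50,000.
    """
    config = SimulationConfig(seed=seed, n_subjects_case=n_samples,
                              n_subjects_control=0,
                              clone_vaf_range=(10 * ERROR_RATE, 1e-2))
    _, truth, results = _run_cohort(config)
    tp = fn = fp = 0
    rel_errors = []
    for s in truth.subjects:
        res = results[s.subject_id]
        true_keys = {(m.target, m.pos, m.alt) for m in s.mutations}
        call_keys = {(c.target, c.pos, c.alt) for c in res.calls}
        tp += len(true_keys & call_keys)
        fn += len(true_keys - call_keys)
        fp += len(call_keys - true_keys)
        for target, est in res.estimate.nt_molecules.items():
            truth_mol = s.nt_molecules[target]
            rel_errors.append((est - truth_mol) / truth_mol)
    rel_errors = np.asarray(rel_errors)
    return {"n_samples": n_samples,
            "true_clones": tp + fn, "detected": tp, "false_calls": fp,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "molecule_relative_bias": float(rel_errors.mean()),
            "molecule_relative_rmse": float(
                np.sqrt((rel_errors ** 2).mean()))}


def auc_recovery_config(seed: int = 0) -> SimulationConfig:
    """Study conditions for one AUC-recovery cohort replication."""
    mc, mn = AUC_STUDY_CLONE_MEANS
    return SimulationConfig(
        seed=seed, n_subjects_case=30, n_subjects_control=29,
        molecules_per_target_nt=2_000, molecules_per_target_is=2_000,
        eccl_rungs=(2_000, 200, 20, 2), reads_per_molecule_mean=25.0,
        clone_mean_case=mc, clone_mean_control=mn,
        clone_vaf_range=(8e-3, 1e-2))


def auc_recovery_study(n_replications: int = 100, seed: int = 0) -> dict:
    """CI coverage of the biomarker AUC over simulated cohorts.

    Each replication simulates a 30/29 cohort, measures every subject's
    prevalence through the full pipeline, and checks whether the DeLong 95%
    CI of the measured AUC covers the configured true AUC (0.850).
    """
    mc, mn = AUC_STUDY_CLONE_MEANS
    true_auc = poisson_mann_whitney_auc(mc, mn)
    rng = np.random.default_rng(seed)
    covered = 0
    aucs = []
    for _ in range(n_replications):
        config = auc_recovery_config(seed=int(rng.integers(2 ** 31)))
        cohort, truth, results = _run_cohort(
            config, min_is1_reads=200, min_target_molecules=500)
        prev = np.array([results[s.subject_id].prevalence
                         for s in truth.subjects], dtype=float)
        labels = (cohort.cancer_status == "CA").astype(int).to_numpy()
        roc = biomarker.roc_auc(prev, labels)
        aucs.append(roc.auc)
        covered += int(roc.ci_low <= true_auc <= roc.ci_high)
    return {"n_replications": n_replications, "true_auc": true_auc,
            "mean_auc": float(np.mean(aucs)),
            "coverage": covered / n_replications}
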