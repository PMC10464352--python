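"""End-to-end orchestration: simulate -> classify -> count -> call -> stats.

Every random stage receives a seed derived from the run configuration, so
any output directory is reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import biomarker, calling, molecules, reads
from .cohort import analyzable_subjects
from .panel import TargetPanel, mock_panel, make_barcodes
from .simulate import (SimulationConfig, SubjectTruth, TruthSet,
                       simulate_cohort, simulate_sample_reads)

log = logging.getLogger("mutprev")


@dataclasses.dataclass
class SampleResult:
    sample_id: str
    estimate: molecules.MoleculeEstimate
    calls: list[calling.VariantCall]
    prevalence: float | None  # None when QC failed


def run_sample(subject: SubjectTruth, panel: TargetPanel,
               config: SimulationConfig,
               rng: np.random.Generator | None = None,
               min_is1_reads: int = molecules.DEFAULT_MIN_IS1_READS,
               min_target_molecules: int =
               molecules.DEFAULT_MIN_TARGET_MOLECULES) -> SampleResult:
    """Simulate one subject's reads and run the full per-sample pipeline."""
    blocks, _ = simulate_sample_reads(subject, panel, config, rng=rng)
    pileups = reads.classify_readset(blocks, panel)
    sp = pileups[subject.subject_id]
    return analyze_sample(sp, panel, eccl_rungs=config.eccl_rungs,
                          eccl_min_reads=config.eccl_min_reads,
                          downsample_seed=subject.read_seed + 1,
                          min_is1_reads=min_is1_reads,
                          min_target_molecules=min_target_molecules)


def analyze_sample(sp: reads.SamplePileup, panel: TargetPanel,
                   eccl_rungs: tuple[int, ...] = (50_000, 5_000, 500, 50),
                   eccl_min_reads: int = 10, downsample_seed: int = 0,
                   alpha: float = calling.DEFAULT_ALPHA,
                   min_is1_reads: int = molecules.DEFAULT_MIN_IS1_READS,
                   min_target_molecules: int =
                   molecules.DEFAULT_MIN_TARGET_MOLECULES) -> SampleResult:
    """Count molecules, down-sample, and call variants for one pileup."""
    est = molecules.estimate_molecules(sp, panel, eccl_rungs=eccl_rungs,
                                       eccl_min_reads=eccl_min_reads)
    est = molecules.qc_sample(sp, est, panel, min_is1_reads=min_is1_reads,
                              min_target_molecules=min_target_molecules)
    if not est.qc_pass:
        log.warning("QC fail %s: %s", sp.sample_id, est.qc_reason)
        return SampleResult(sp.sample_id, est, [], None)
    thinned = molecules.downsample_to_molecules(sp, est, downsample_seed)
    lob = calling.estimate_lob(sp, panel)
    calls = calling.call_variants(thinned, lob, panel, alpha=alpha)
    prev = biomarker.mutation_prevalence(calls, panel.analyzable_bp)
    return SampleResult(sp.sample_id, est, calls, prev)


def run_simulated_study(config: SimulationConfig,
                        panel: TargetPanel | None = None,
                        **sample_kwargs) -> tuple[pd.DataFrame, TruthSet,
                                                  dict[str, SampleResult]]:
    """Simulate a cohort and push every subject through the pipeline.

    Returns the cohort table augmented with the measured biomarker, the
    ground truth, and per-sample results.
    """
    if panel is None:
        panel = mock_panel()
    cohort, truth = simulate_cohort(config, panel)
    if not panel.barcodes:
        panel = panel.with_barcodes(make_barcodes(
            [s.subject_id for s in truth.subjects], seed=config.seed + 101))
    results: dict[str, SampleResult] = {}
    measured = []
    for subject in truth.subjects:
        res = run_sample(subject, panel, config, **sample_kwargs)
        results[subject.subject_id] = res
        measured.append(res.prevalence)
    cohort = cohort.copy()
    cohort["tp53_prevalence"] = measured
    cohort["qc_pass"] = [results[s].estimate.qc_pass
                         for s in cohort.subject_id]
    return cohort, truth, results


def analyze_cohort(df: pd.DataFrame, prs_column: str | None = None,
                   seed: int = 0) -> dict:
    """Cohort-level biomarker statistics from a subject table.

    Requires ``cancer_status`` and ``tp53_prevalence`` columns; subjects
    with a missing biomarker are excluded (their count is reported).  When
    ``prs_column`` names a demographic risk-probability column, the CBM and
    AUC comparisons are added for subjects with both scores.
    """
    an = analyzable_subjects(df)
    ca = an[an.cancer_status == "CA"].tp53_prevalence.to_numpy()
    nc = an[an.cancer_status == "NC"].tp53_prevalence.to_numpy()
    labels = (an.cancer_status == "CA").astype(int).to_numpy()
    roc = biomarker.roc_auc(an.tp53_prevalence.to_numpy(), labels)
    h, kw_p = biomarker.kruskal_wallis([ca, nc])
    stats_out = {
        "n_subjects": int(len(df)),
        "n_analyzable": int(len(an)),
        "n_excluded_missing_biomarker": int(len(df) - len(an)),
        "groups": biomarker.group_prevalence_summary(df),
        "kruskal_wallis": {"H": h, "p": kw_p},
        "wilcoxon_p": biomarker.wilcoxon_rank_sum(ca, nc),
        "tp53_auc": {"auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
                     "youden_cutoff": roc.youden_cutoff},
    }
    if "smoking_status" in an.columns and "age" in an.columns:
        cases = df[df.cancer_status == "CA"]
        smokers = an[(an.cancer_status == "NC") &
                     (an.smoking_status != "Never")]
        stats_out["demographics"] = {
            "case_mean_age": float(cases.age.mean()),
            "case_mean_pack_years": float(cases.pack_years.mean()),
            "control_smoker_mean_pack_years": float(
                smokers.pack_years.mean()),
        }
    if prs_column is not None:
        sub = an.dropna(subset=[prs_column])
        prs = sub[prs_column].to_numpy(dtype=float)
        prev = sub.tp53_prevalence.to_numpy(dtype=float)
        lab = (sub.cancer_status == "CA").astype(int).to_numpy()
        cbm = np.array([biomarker.cbm_probability(p, t)
                        for p, t in zip(prs, prev)])
        roc_cbm = biomarker.roc_auc(cbm, lab)
        roc_prs = biomarker.roc_auc(prs, lab)
        stats_out["cbm"] = {
            "n": int(len(sub)),
            "auc": roc_cbm.auc, "ci": [roc_cbm.ci_low, roc_cbm.ci_high],
            "prs_auc": roc_prs.auc,
            "p_cbm_vs_prs": biomarker.compare_auc_paired(
                cbm, prs, lab, seed=seed),
            "p_cbm_vs_tp53": biomarker.compare_auc_paired(
                cbm, prev, lab, seed=seed),
            "tp53_scale": biomarker.CbmModel().tp53_scale,
        }
    return stats_out


def run_pipeline(config: SimulationConfig, outdir: str,
                 panel: TargetPanel | None = None, **sample_kwargs) -> dict:
    """Full run: simulate, analyze every sample, write outputs + stats JSON.

    Writes per-sample VCFs, a molecule-estimate TSV, the cohort biomarker
    TSV, ``statistics.json``, and a run log carrying the config hash.
    """
    os.makedirs(outdir, exist_ok=True)
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    handler = logging.FileHandler(os.path.join(outdir, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    try:
        cohort, truth, results = run_simulated_study(config, panel,
                                                     **sample_kwargs)
        vcf_dir = os.path.join(outdir, "vcf")
        os.makedirs(vcf_dir, exist_ok=True)
        est_rows = []
        for sid, res in results.items():
            calling.write_vcf(res.calls, os.path.join(vcf_dir, f"{sid}.vcf"))
            est = res.estimate
            est_rows.append({
                "sample_id": sid,
                "is1_adjusted_molecules": est.is1_adjusted_molecules,
                "scgb1a1_nt_molecules": est.scgb1a1_nt_molecules,
                **{f"nt_molecules_{t}": v
                   for t, v in est.nt_molecules.items()},
                "qc_pass": est.qc_pass, "qc_reason": est.qc_reason or ""})
        pd.DataFrame(est_rows).to_csv(
            os.path.join(outdir, "molecule_estimates.tsv"), sep="\t",
            index=False)
        cohort.to_csv(os.path.join(outdir, "cohort_biomarker.tsv"),
                      sep="\t", index=False)
        stats_out = analyze_cohort(cohort)
        cfg_json = json.dumps(
            {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in dataclasses.asdict(config).items()},
            sort_keys=True, default=str)
        stats_out["config_sha256"] = hashlib.sha256(
            cfg_json.encode()).hexdigest()
        with open(os.path.join(outdir, "statistics.json"), "w") as fh:
            json.dump(stats_out, fh, indent=2, sort_keys=True)
        log.info("run complete: %d samples, config %s",
                 len(results), stats_out["config_sha256"][:12])
        return stats_out
    finally:
        log.removeHandler(handler)
        handler.close()
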