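"""The mutation-prevalence biomarker and its cohort-level statistics.

The biomarker is the number of unique TP53 mutation clones observed in a
specimen divided by the 193 analyzable bases (mutations/bp).  Cohort
analyses: nonparametric group comparisons (Kruskal-Wallis, Wilcoxon rank-sum
with continuity correction), ROC AUC as the Mann-Whitney probability with
half-credit for ties plus a DeLong confidence interval and Youden-optimal
cutoff, substitution-class and hotspot enrichment, a combined biomarker
(CBM) logistic model with fixed published-style coefficients, and a paired
bootstrap comparison of two AUCs on the same subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calling import VariantCall
from .panel import SIGNATURE_CLASSES

ANALYZABLE_BP = 193


def mutation_prevalence(calls: list[VariantCall],
                        analyzable_bp: int = ANALYZABLE_BP) -> float:
    """Unique mutation clones per analyzable base (mutations/bp)."""
    unique = {(c.target, c.pos, c.alt) for c in calls}
    return len(unique) / analyzable_bp


def group_prevalence_summary(cohort) -> dict[str, dict[str, float]]:
    """Group means of the biomarker: cases, all controls, and the control
    smoker / never-smoker subgroups.  Subjects with a missing biomarker are
    excluded."""
    df = cohort.dropna(subset=["tp53_prevalence"])
    groups = {
        "CA": df[df.cancer_status == "CA"],
        "NC": df[df.cancer_status == "NC"],
    }
    for name, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"empty group {name}")
    if "smoking_status" in df.columns:
        # the Fig-1a style subgrouping, available when smoking data exist
        nc = groups["NC"]
        for name, g in (("NC_smoker", nc[nc.smoking_status != "Never"]),
                        ("NC_never", nc[nc.smoking_status == "Never"])):
            if len(g):
                groups[name] = g
    return {name: {"n": int(len(g)),
                   "mean_prevalence": float(g.tp53_prevalence.mean())}
            for name, g in groups.items()}


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with k-1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_rank_sum(x, y, continuity: bool = True) -> float:
    """Two-sided rank-sum p-value, normal approximation with tie-corrected
    variance and 0.5 continuity correction (the conventional default of
    field statistical software)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # degenerate: no rank information
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             use_continuity=continuity, method="asymptotic")
    return float(res.pvalue)


# ----------------------------------------------------------------- ROC/AUC

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    youden_cutoff: float
    youden_sensitivity: float
    youden_specificity: float
    thresholds: np.ndarray  # candidate cutoffs (ascending)
    sensitivity: np.ndarray  # P(score >= cutoff | case)
    specificity: np.ndarray  # P(score < cutoff | control)
    method: str = "mann-whitney/delong"


def _mann_whitney_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    wins = 0.0
    for c in cases:
        wins += (c > controls).sum() + 0.5 * (c == controls).sum()
    return wins / (cases.size * controls.size)


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong variance of the AUC via placement values."""
    v10 = np.array([(c > controls).mean() + 0.5 * (c == controls).mean()
                    for c in cases])
    v01 = np.array([(cases > d).mean() + 0.5 * (cases == d).mean()
                    for d in controls])
    m, n = cases.size, controls.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels, ci_method: str = "delong",
            n_boot: int = 2000, seed: int = 0) -> RocResult:
    """AUC (Mann-Whitney with half-credit ties), 95% CI, and Youden cutoff.

    The Youden cutoff maximizes sensitivity + specificity - 1 over the rule
    "positive iff score >= cutoff"; ties between maximizers resolve to the
    smallest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases, controls = scores[labels == 1], scores[labels == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    auc = _mann_whitney_auc(cases, controls)
    z = 1.959963984540054
    if ci_method == "delong":
        se = math.sqrt(_delong_variance(cases, controls))
        if 0.0 < auc < 1.0 and se > 0.0:
            # Wald interval on the logit scale: respects the (0,1) range and
            # markedly better calibrated than the raw-scale interval for
            # small, tied samples
            logit = math.log(auc / (1.0 - auc))
            se_logit = se / (auc * (1.0 - auc))
            lo = 1.0 / (1.0 + math.exp(-(logit - z * se_logit)))
            hi = 1.0 / (1.0 + math.exp(-(logit + z * se_logit)))
        else:
            lo = max(auc - z * se, 0.0)
            hi = min(auc + z * se, 1.0)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            cb = cases[rng.integers(0, cases.size, cases.size)]
            db = controls[rng.integers(0, controls.size, controls.size)]
            reps[b] = _mann_whitney_auc(cb, db)
        lo, hi = np.quantile(reps, [0.025, 0.975])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    thresholds = np.unique(scores)
    sens = np.array([(cases >= t).mean() for t in thresholds])
    spec = np.array([(controls < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    return RocResult(auc=float(auc), ci_low=float(lo), ci_high=float(hi),
                     youden_cutoff=float(thresholds[best]),
                     youden_sensitivity=float(sens[best]),
                     youden_specificity=float(spec[best]),
                     thresholds=thresholds, sensitivity=sens,
                     specificity=spec,
                     method=f"mann-whitney/{ci_method}")


def write_roc_points(res: RocResult, path) -> None:
    """ROC curve points as TSV (cutoff, sensitivity, specificity)."""
    with open(path, "w") as fh:
        fh.write("cutoff\tsensitivity\tspecificity\n")
        for t, se, sp in zip(res.thresholds, res.sensitivity,
                             res.specificity):
            fh.write(f"{t:.6g}\t{se:.6g}\t{sp:.6g}\n")


def compare_auc_paired(scores_a, scores_b, labels, n_boot: int = 2000,
                       seed: int = 0, method: str = "bootstrap") -> float:
    """Two-sided p-value for a difference between two AUCs measured on the
    same subjects.

    Default: paired stratified bootstrap of the AUC difference (cases and
    controls resampled jointly for both scores).  ``method='delong'`` uses
    the paired DeLong normal test instead.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.size != b.size or a.size != labels.size:
        raise ValueError("scores_a, scores_b and labels must align")
    ca, cb = a[labels == 1], b[labels == 1]
    da, db = a[labels == 0], b[labels == 0]
    if method == "delong":
        return _delong_paired_p(ca, da, cb, db)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    m, n = ca.size, da.size
    for i in range(n_boot):
        ic = rng.integers(0, m, m)
        id_ = rng.integers(0, n, n)
        diffs[i] = (_mann_whitney_auc(ca[ic], da[id_]) -
                    _mann_whitney_auc(cb[ic], db[id_]))
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return float(min(p, 1.0))


def _delong_paired_p(ca, da, cb, db) -> float:
    v10a = np.array([(c > da).mean() + 0.5 * (c == da).mean() for c in ca])
    v01a = np.array([(ca > d).mean() + 0.5 * (ca == d).mean() for d in da])
    v10b = np.array([(c > db).mean() + 0.5 * (c == db).mean() for c in cb])
    v01b = np.array([(cb > d).mean() + 0.5 * (cb == d).mean() for d in db])
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = ca.size, da.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + \
          (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# -------------------------------------------------------------------- CBM

@dataclass(frozen=True)
class CbmModel:
    """Combined biomarker: logistic model over the demographic risk
    probability (PRS.con, on [0,1]) and the TP53 biomarker.

    With ``tp53_scale='count'`` (default) the TP53 term enters as the unique
    mutation count (prevalence x 193); with ``'prevalence'`` it enters as
    mutations/bp.  Coefficients are fixed; refitting is deliberate, explicit
    behavior elsewhere, never implicit here.
    """

    intercept: float = -3.165853
    beta_prs: float = 29.31218
    beta_tp53: float = 0.5462315
    tp53_scale: str = "count"


def cbm_probability(prs_con: float, tp53: float,
                    model: CbmModel | None = None,
                    tp53_is_prevalence: bool = True) -> float:
    """Logistic CBM probability for one subject.

    ``tp53`` is the biomarker in mutations/bp when ``tp53_is_prevalence``
    (converted per ``model.tp53_scale``); missing inputs yield NaN, and such
    subjects are dropped from CBM analyses.
    """
    if model is None:
        model = CbmModel()
    if prs_con is None or tp53 is None or \
            not (np.isfinite(prs_con) and np.isfinite(tp53)):
        return float("nan")
    if not 0.0 <= prs_con <= 1.0:
        raise ValueError("prs_con must be a probability on [0, 1]")
    t = tp53 * ANALYZABLE_BP if (tp53_is_prevalence and
                                 model.tp53_scale == "count") else tp53
    xb = model.intercept + model.beta_prs * prs_con + model.beta_tp53 * t
    return float(1.0 / (1.0 + math.exp(-xb)))


# -------------------------------------------------------- enrichment tests

def per_subject_class_prevalence(calls: list[VariantCall],
                                 analyzable_bp: int = ANALYZABLE_BP
                                 ) -> dict[str, float]:
    """Biomarker partitioned by substitution class (sums to the total)."""
    out = {c: 0.0 for c in SIGNATURE_CLASSES}
    seen = set()
    for c in calls:
        key = (c.target, c.pos, c.alt)
        if key in seen:
            continue
        seen.add(key)
        out[c.sig_class] += 1.0 / analyzable_bp
    return out


def signature_enrichment(subject_calls: dict[str, list[VariantCall]],
                         labels: dict[str, str],
                         classes: tuple[str, ...] = ("C>A", "C>T", "T>C",
                                                     "other"),
                         analyzable_bp: int = ANALYZABLE_BP) -> dict:
    """Per-class case/control comparison of class-specific prevalence.

    Kruskal-Wallis per class, Bonferroni-adjusted over the number of classes
    actually tested; a class with no calls anywhere is reported with p = 1
    and not counted in the correction.
    """
    per_class: dict[str, dict[str, list[float]]] = {
        cls: {"CA": [], "NC": []} for cls in classes}
    for sid, calls in subject_calls.items():
        prev = per_subject_class_prevalence(calls, analyzable_bp)
        for cls in classes:
            per_class[cls][labels[sid]].append(prev[cls])
    tested = [cls for cls in classes
              if any(v > 0 for g in per_class[cls].values() for v in g)]
    results = {}
    for cls in classes:
        ca, nc = per_class[cls]["CA"], per_class[cls]["NC"]
        if cls not in tested:
            results[cls] = {"p": 1.0, "p_adjusted": 1.0,
                            "mean_ca": 0.0, "mean_nc": 0.0}
            continue
        _, p = kruskal_wallis([ca, nc])
        results[cls] = {
            "p": p, "p_adjusted": min(1.0, p * len(tested)),
            "mean_ca": float(np.mean(ca)) if ca else 0.0,
            "mean_nc": float(np.mean(nc)) if nc else 0.0}
    return results


def hotspot_enrichment(subject_calls: dict[str, list[VariantCall]],
                       labels: dict[str, str]) -> dict:
    """Proportion of calls at hotspot sites per group + Fisher exact test on
    the 2x2 (hotspot yes/no x case/control) table."""
    table = {"CA": [0, 0], "NC": [0, 0]}  # [at hotspot, elsewhere]
    for sid, calls in subject_calls.items():
        g = labels[sid]
        for c in calls:
            if c.hotspot is None:
                continue
            table[g][0 if c.hotspot else 1] += 1
    out: dict = {"table": table}
    for g in ("CA", "NC"):
        total = sum(table[g])
        out[f"proportion_{g}"] = table[g][0] / total if total else float("nan")
    if sum(table["CA"]) == 0 and sum(table["NC"]) == 0:
        out["p"] = float("nan")
        return out
    _, p = stats.fisher_exact([table["CA"], table["NC"]])
    out["p"] = float(p)
    return out
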