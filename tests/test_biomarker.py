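"""Biomarker statistics: prevalence, rank tests, ROC/AUC, CBM, enrichment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutprev.biomarker import (CbmModel, cbm_probability, compare_auc_paired,
                               group_prevalence_summary, hotspot_enrichment,
                               kruskal_wallis, mutation_prevalence,
                               per_subject_class_prevalence, roc_auc,
                               signature_enrichment, wilcoxon_rank_sum)
from mutprev.calling import VariantCall
from mutprev.cohort import load_cohort_table


def _call(target, pos, alt, sig_class="C>A", hotspot=None):
    return VariantCall(target=target, pos=pos, chrom="chr17",
                       genomic_pos=1000 + pos, ref="C", alt=alt,
                       nt_molecules=20, nt_depth=50_000, vaf=4e-4, lob=1e-5,
                       p_value=1e-9, significant=True,
                       passes_molecule_filter=True, passes_vaf_filter=True,
                       sig_class=sig_class, hotspot=hotspot)


def test_prevalence_counts_unique_clones():
    assert mutation_prevalence([]) == 0.0
    one = [_call("TP53.5", 30, "A")]
    assert mutation_prevalence(one) == pytest.approx(1 / 193)
    dup = one + [_call("TP53.5", 30, "A")]  # recurrent clone counts once
    assert mutation_prevalence(dup) == pytest.approx(1 / 193)
    two = one + [_call("TP53.5", 30, "T")]  # same site, different alt
    assert mutation_prevalence(two) == pytest.approx(2 / 193)


def test_group_prevalence_summary_on_fixture():
    df = load_cohort_table()
    out = group_prevalence_summary(df)
    assert out["CA"]["n"] == 30 and out["NC"]["n"] == 29
    assert out["CA"]["mean_prevalence"] == pytest.approx(0.027, abs=5e-4)
    assert out["NC"]["mean_prevalence"] == pytest.approx(0.006, abs=5e-4)
    assert out["NC_smoker"]["n"] == 21 and out["NC_never"]["n"] == 8


def test_identical_groups_give_h0_p1():
    assert kruskal_wallis([[1.0, 1.0], [1.0, 1.0, 1.0]]) == (0.0, 1.0)


def test_kruskal_wallis_matches_hand_ranked_oracle():
    groups = [[1.2, 3.4, 5.6], [2.1, 4.3, 6.5], [0.7, 7.8, 8.9]]
    flat = sorted(v for g in groups for v in g)
    ranks = {v: i + 1 for i, v in enumerate(flat)}  # no ties
    n = len(flat)
    h = 12 / (n * (n + 1)) * sum(
        sum(ranks[v] for v in g) ** 2 / len(g) for g in groups) - 3 * (n + 1)
    got_h, got_p = kruskal_wallis(groups)
    assert got_h == pytest.approx(h)
    from scipy.stats import chi2
    assert got_p == pytest.approx(chi2.sf(h, 2))


@pytest.mark.parametrize("x,y", [
    ([1.0, 2.0, 3.0, 7.0, 9.0, 12.0], [4.0, 5.0, 6.0, 8.0, 10.0, 11.0]),
    ([1.0, 2.0, 3.0, 4.0, 9.0, 10.0], [5.0, 6.0, 7.0, 8.0, 11.0, 12.0]),
])
def test_wilcoxon_close_to_exact_permutation_null(x, y):
    # no-ties set: compare against full enumeration of the rank-sum null
    n = len(x) + len(y)
    pooled = sorted(x + y)
    obs = sum(pooled.index(v) + 1 for v in x)
    mean = len(x) * (n + 1) / 2
    count = sum(
        1 for idx in itertools.combinations(range(n), len(x))
        if abs(sum(i + 1 for i in idx) - mean) >= abs(obs - mean))
    exact = count / math.comb(n, len(x))
    assert abs(wilcoxon_rank_sum(x, y) - exact) <= 0.02


def test_wilcoxon_degenerate_ties():
    assert wilcoxon_rank_sum([1.0], [1.0]) == 1.0


def test_auc_trivial_cases():
    assert roc_auc([1, 2, 3, 10, 11, 12],
                   [0, 0, 0, 1, 1, 1]).auc == 1.0
    assert roc_auc([5.0] * 6, [0, 0, 0, 1, 1, 1]).auc == 0.5


def _brute_force_auc(scores, labels):
    cases = [s for s, l in zip(scores, labels) if l == 1]
    controls = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if c > d else 0.5 if c == d else 0.0
               for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


@settings(max_examples=40, deadline=None)
@given(st.data())
def test_auc_equals_brute_force_pairwise(data):
    n1 = data.draw(st.integers(1, 25))
    n0 = data.draw(st.integers(1, 25))
    vals = st.integers(0, 8)  # heavy ties on purpose
    cases = data.draw(st.lists(vals, min_size=n1, max_size=n1))
    controls = data.draw(st.lists(vals, min_size=n0, max_size=n0))
    scores = cases + controls
    labels = [1] * n1 + [0] * n0
    assert roc_auc(scores, labels).auc == pytest.approx(
        _brute_force_auc(scores, labels))


def test_auc_invariant_under_increasing_transform():
    df = load_cohort_table().dropna(subset=["tp53_prevalence"])
    labels = (df.cancer_status == "CA").astype(int).to_numpy()
    prev = df.tp53_prevalence.to_numpy()
    assert roc_auc(prev, labels).auc == roc_auc(prev * 193, labels).auc


def test_youden_cutoff_and_tie_break():
    res = roc_auc([0.0, 1.0, 2.0, 3.0], [0, 0, 1, 1])
    assert res.youden_cutoff == 2.0
    assert res.youden_sensitivity == 1.0 and res.youden_specificity == 1.0
    flat = roc_auc([5.0, 5.0, 5.0, 5.0], [0, 0, 1, 1])
    assert flat.youden_cutoff == 5.0  # smallest maximizer among ties


def test_one_class_absent_is_error():
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_cbm_printed_formula_values():
    assert cbm_probability(0.0, 0.0) == pytest.approx(
        1 / (1 + math.exp(3.165853)))
    assert cbm_probability(1.0, 0.0) == pytest.approx(
        1 / (1 + math.exp(-(29.31218 - 3.165853))))
    assert cbm_probability(1.0, 0.0) > 0.999999999


def test_cbm_monotone_and_balanced_point():
    base = cbm_probability(0.2, 5 / 193)
    assert cbm_probability(0.3, 5 / 193) > base
    assert cbm_probability(0.2, 6 / 193) > base
    t_star = 3.165853 / 0.5462315  # count solving the linear predictor = 0
    assert cbm_probability(0.0, t_star / 193) == pytest.approx(0.5)
    assert 0.0 < base < 1.0


def test_cbm_count_scale_is_default():
    assert CbmModel().tp53_scale == "count"
    # a prevalence of 0.027 enters as ~5.2 mutations, not as 0.027
    p_count = cbm_probability(0.0, 0.027)
    p_prev = cbm_probability(0.0, 0.027,
                             model=CbmModel(tp53_scale="prevalence"))
    assert p_count > p_prev


def test_cbm_missing_input_propagates_nan():
    assert math.isnan(cbm_probability(float("nan"), 0.01))
    with pytest.raises(ValueError):
        cbm_probability(1.5, 0.01)


def test_compare_auc_identical_scores_p1():
    scores = list(range(20))
    labels = [0] * 10 + [1] * 10
    assert compare_auc_paired(scores, scores, labels, seed=1) == 1.0


def test_compare_auc_deterministic_given_seed(rng):
    a = rng.normal(size=40) + np.repeat([0, 1.2], 20)
    b = rng.normal(size=40)
    labels = np.repeat([0, 1], 20)
    p1 = compare_auc_paired(a, b, labels, seed=5)
    p2 = compare_auc_paired(a, b, labels, seed=5)
    assert p1 == p2


def test_compare_auc_length_mismatch():
    with pytest.raises(ValueError, match="align"):
        compare_auc_paired([1, 2], [1, 2, 3], [0, 1])


def test_compare_auc_power_when_difference_is_real(rng):
    # true delta-AUC ~ 0.15 at n = 30/29 should reject more than half the
    # time at alpha 0.05
    rejections = 0
    n_rep = 60
    for _ in range(n_rep):
        labels = np.array([1] * 30 + [0] * 29)
        strong = np.where(labels == 1, rng.normal(1.9, 1, 59),
                          rng.normal(0, 1, 59))  # AUC ~ 0.91
        weak = np.where(labels == 1, rng.normal(0.75, 1, 59),
                        rng.normal(0, 1, 59))  # AUC ~ 0.70
        p = compare_auc_paired(strong, weak, labels, n_boot=400,
                               seed=int(rng.integers(2 ** 31)))
        rejections += p < 0.05
    assert rejections / n_rep > 0.5


def test_delong_paired_variant_available():
    labels = np.repeat([0, 1], 15)
    rng = np.random.default_rng(2)
    a = labels * 1.5 + rng.normal(size=30)
    b = rng.normal(size=30)
    p = compare_auc_paired(a, b, labels, method="delong")
    assert 0.0 <= p <= 1.0


def test_class_prevalence_partitions_total():
    calls = [_call("TP53.5", 30, "A", "C>A"),
             _call("TP53.5", 40, "T", "C>T"),
             _call("TP53.6", 50, "G", "other")]
    per_class = per_subject_class_prevalence(calls)
    assert sum(per_class.values()) == pytest.approx(
        mutation_prevalence(calls))


def test_signature_enrichment_null_and_enriched():
    labels = {}
    subject_calls = {}
    for i in range(30):
        sid = f"C{i}"
        labels[sid] = "CA"
        subject_calls[sid] = [_call("TP53.5", 30 + j, "A", "C>A")
                              for j in range(5)]
    for i in range(29):
        sid = f"N{i}"
        labels[sid] = "NC"
        subject_calls[sid] = ([_call("TP53.5", 30, "A", "C>A")]
                              if i % 3 == 0 else [])
    out = signature_enrichment(subject_calls, labels)
    assert out["C>A"]["p_adjusted"] < 0.05
    assert out["T>C"]["p"] == 1.0  # never observed -> untested
    empty = signature_enrichment({sid: [] for sid in labels}, labels)
    assert all(v["p"] == 1.0 for v in empty.values())


def test_hotspot_enrichment_fisher_matches_hypergeometric_oracle():
    from scipy.stats import hypergeom

    labels = {"ca": "CA", "nc": "NC"}
    subject_calls = {
        "ca": [_call("TP53.5", 25 + i, "A", hotspot=i < 20)
               for i in range(25)],
        "nc": [_call("TP53.6", 25 + i, "A", hotspot=i < 5)
               for i in range(25)],
    }
    out = hotspot_enrichment(subject_calls, labels)
    assert out["table"] == {"CA": [20, 5], "NC": [5, 20]}
    # brute-force two-sided Fisher: sum of all table probabilities <= obs
    M, n, N = 50, 25, 25  # total, hotspot total, CA total
    probs = [hypergeom.pmf(k, M, n, N) for k in range(26)]
    obs = probs[20]
    expected = sum(p for p in probs if p <= obs * (1 + 1e-9))
    assert out["p"] == pytest.approx(expected)


def test_hotspot_enrichment_degenerate_cases():
    labels = {"a": "CA", "b": "NC"}
    all_hot = {"a": [_call("TP53.5", 30, "A", hotspot=True)],
               "b": [_call("TP53.5", 31, "A", hotspot=True)]}
    out = hotspot_enrichment(all_hot, labels)
    assert out["proportion_CA"] == 1.0 and out["proportion_NC"] == 1.0
    assert out["p"] == 1.0
    none_flagged = {"a": [_call("TP53.5", 30, "A", hotspot=False)],
                    "b": []}
    out2 = hotspot_enrichment(none_flagged, labels)
    assert out2["proportion_CA"] == 0.0
    assert math.isnan(out2["proportion_NC"])
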