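"""ROC/C-statistic machinery against exhaustive and resampling oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import modytree as mt


def brute_force_auc(pos, neg):
    """Exhaustive tie-aware pairwise count over all (pos, neg) pairs."""
    pos = np.asarray(pos, float)[:, None]
    neg = np.asarray(neg, float)[None, :]
    return float(np.mean((pos > neg) + 0.5 * (pos == neg)))


def test_perfect_separation():
    assert mt.c_statistic([3, 4], [1, 2]).auc == 1.0


def test_full_overlap_with_ties():
    assert mt.c_statistic([1, 2], [1, 2]).auc == 0.5


@pytest.mark.parametrize("trial", range(25))
def test_pairwise_oracle_with_ties(trial):
    rng = np.random.default_rng(1000 + trial)
    m, n = rng.integers(2, 51, 2)
    pos = np.round(rng.normal(0.4, 1.0, m), 1)  # rounding forces ties
    neg = np.round(rng.normal(0.0, 1.0, n), 1)
    res = mt.c_statistic(pos, neg)
    assert res.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
    assert res.ci_low <= res.auc <= res.ci_high
    assert res.variance >= 0
    # trapezoidal area under the returned curve is the same number
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(m), np.zeros(n)]).astype(bool)
    assert mt.roc_curve(scores, labels).auc_trapezoid() == pytest.approx(res.auc, abs=1e-12)


def test_empty_class_is_an_error():
    with pytest.raises(ValueError):
        mt.c_statistic([], [1.0])


@given(
    pos=st.lists(st.integers(-50, 50), min_size=1, max_size=30),
    neg=st.lists(st.integers(-50, 50), min_size=1, max_size=30),
)
def test_monotone_transform_invariance_and_complement(pos, neg):
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    base = mt.c_statistic(pos, neg).auc
    affine = mt.c_statistic(2.0 * pos + 1.0, 2.0 * neg + 1.0).auc
    expo = mt.c_statistic(np.exp(pos / 25.0), np.exp(neg / 25.0)).auc
    assert affine == pytest.approx(base, abs=1e-12)
    assert expo == pytest.approx(base, abs=1e-12)
    assert mt.c_statistic(-pos, -neg).auc == pytest.approx(1.0 - base, abs=1e-12)


def test_delong_self_comparison_is_null():
    rng = np.random.default_rng(0)
    s = rng.standard_normal(40)
    labels = np.arange(40) < 15
    z, p = mt.delong_paired_test(s, s, labels)
    assert (z, p) == (0.0, 1.0)


def test_delong_degenerate_unequal_aucs_raises():
    labels = np.array([True, True, False, False])
    a = np.array([2.0, 3.0, 0.0, 1.0])  # AUC 1, zero variance
    b = np.array([0.0, 1.0, 2.0, 3.0])  # AUC 0, zero variance
    with pytest.raises(ValueError):
        mt.delong_paired_test(a, b, labels)


def test_delong_variance_matches_paired_bootstrap():
    """The DeLong variance of an AUC difference agrees with a stratified
    paired bootstrap (2000 resamples) within 15% on a fixed n=60 cohort."""
    rng = np.random.default_rng(7)
    n = 60
    labels = np.arange(n) < 30
    latent = rng.standard_normal(n) + 0.8 * labels
    a = latent + 0.5 * rng.standard_normal(n)
    b = latent + 0.7 * rng.standard_normal(n)

    def auc_diff(idx_pos, idx_neg):
        idx = np.concatenate([idx_pos, idx_neg])
        lab = np.concatenate([np.ones(len(idx_pos)), np.zeros(len(idx_neg))]).astype(bool)
        aa = mt.auc_from_labels(a[idx], lab).auc
        ab = mt.auc_from_labels(b[idx], lab).auc
        return aa - ab

    pos_idx, neg_idx = np.where(labels)[0], np.where(~labels)[0]
    diffs = [
        auc_diff(rng.choice(pos_idx, size=30), rng.choice(neg_idx, size=30))
        for _ in range(2000)
    ]
    boot_var = np.var(diffs, ddof=1)

    from modytree.roc_stats import delong_difference_variance

    _, delong_var = delong_difference_variance(a, b, labels)
    assert delong_var == pytest.approx(boot_var, rel=0.15)


def test_delong_variance_shrinks_with_n():
    rng = np.random.default_rng(5)

    def var_at(n):
        pos = rng.standard_normal(n) + 1.0
        neg = rng.standard_normal(n)
        return mt.c_statistic(pos, neg).variance

    assert var_at(2000) < var_at(50)


def test_curve_endpoints_and_label_flip():
    rng = np.random.default_rng(2)
    scores = rng.standard_normal(80)
    labels = rng.random(80) < 0.4
    curve = mt.roc_curve(scores, labels)
    assert (curve.sensitivity[0], curve.specificity[0]) == (1.0, 0.0)
    assert (curve.sensitivity[-1], curve.specificity[-1]) == (0.0, 1.0)
    assert np.all(np.diff(curve.sensitivity) <= 0)
    flipped = mt.roc_curve(scores, ~labels)
    assert flipped.auc_trapezoid() == pytest.approx(
        1.0 - curve.auc_trapezoid(), abs=1e-12
    )


def test_single_class_curve_is_an_error():
    with pytest.raises(ValueError):
        mt.roc_curve([1.0, 2.0], [True, True])


@pytest.mark.parametrize("trial", range(10))
def test_youden_matches_brute_force(trial):
    rng = np.random.default_rng(300 + trial)
    scores = np.round(rng.normal(size=10), 1)
    labels = np.zeros(10, dtype=bool)
    labels[rng.choice(10, 4, replace=False)] = True
    if labels.all() or not labels.any():
        pytest.skip("degenerate draw")
    curve = mt.roc_curve(scores, labels)
    choice = mt.select_threshold(curve)
    # brute force over every cutpoint with the inclusive >= convention
    best_j, best_t = -np.inf, None
    for t in np.concatenate([np.unique(scores), [np.inf]]):
        sens = np.mean(scores[labels] >= t)
        spec = np.mean(scores[~labels] < t)
        j = sens + spec - 1.0
        if j > best_j:  # strict: keeps the smallest threshold on ties
            best_j, best_t = j, t
    assert choice.youden_j == pytest.approx(best_j, abs=1e-12)
    assert choice.threshold == best_t


def test_perfectly_separated_youden():
    scores = np.array([0.0, 1.0, 10.0, 11.0])
    labels = np.array([False, False, True, True])
    choice = mt.select_threshold(mt.roc_curve(scores, labels))
    assert choice.youden_j == pytest.approx(1.0)
    assert choice.threshold == 10.0  # smallest cutpoint achieving J = 1


def test_all_identical_scores_degenerate():
    choice = mt.select_threshold(mt.roc_curve([5.0] * 6, [1, 0, 1, 0, 1, 0]))
    assert choice.youden_j == pytest.approx(0.0)
    assert (choice.sensitivity, choice.specificity) == (1.0, 0.0)


def test_fixed_threshold_performance():
    scores = np.array([0.2, 0.7, 1.4, 2.9])
    labels = np.array([False, False, True, True])
    perf = mt.threshold_performance(scores, labels, 1.4, inclusive=True)
    assert (perf.sensitivity, perf.specificity) == (1.0, 1.0)
    strict = mt.threshold_performance(scores, labels, 1.4, inclusive=False)
    assert (strict.sensitivity, strict.specificity) == (0.5, 1.0)
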