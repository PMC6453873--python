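"""Discrimination machinery: C-statistic, DeLong inference, ROC curves.

The C-statistic (area under the ROC curve) is computed tie-aware as the
Mann–Whitney probability ``P(X > Y) + ½·P(X = Y)`` for a random positive
score X and negative score Y. Variances and the paired comparison test use
DeLong's structural components: per-positive placements ``V10`` and
per-negative placements ``V01``, whose empirical covariances yield a
nonparametric variance for a single AUC and for a difference of two AUCs
measured on the *same* subjects. All quantities are rank based, hence
invariant under strictly monotone transforms of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AucResult",
    "RocCurve",
    "ThresholdChoice",
    "c_statistic",
    "delong_paired_test",
    "delong_difference_variance",
    "roc_curve",
    "select_threshold",
    "threshold_performance",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class AucResult:
    """C-statistic with DeLong variance and 95% Wald CI (clipped to [0, 1])."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"auc outside [0, 1]: {self.auc}")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must bracket the AUC")


@dataclass(frozen=True)
class RocCurve:
    """Stepwise ROC curve over the unique score cutpoints.

    ``thresholds`` ascend and end with a +inf sentinel; at threshold *t* a
    subject is called positive when its score is ≥ *t* (higher = positive).
    The first point is therefore (sensitivity 1, specificity 0) and the last
    (0, 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def auc_trapezoid(self) -> float:
        """Area under the curve by the trapezoidal rule (equals the
        tie-aware pairwise C-statistic)."""
        fpr = 1.0 - self.specificity
        tpr = self.sensitivity
        # points run from (fpr 1, tpr 1) down to (0, 0); integrate ascending
        return float(np.trapezoid(tpr[::-1], fpr[::-1]))


@dataclass(frozen=True)
class ThresholdChoice:
    threshold: float
    sensitivity: float
    specificity: float
    criterion: str  # "youden" or "fixed"

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Tie-aware AUC plus DeLong structural components via midranks."""
    m, n = pos.size, neg.size
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n          # placement of each positive among negatives
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # placement of each negative among positives
    auc = float(v10.mean())
    return auc, v10, v01


def c_statistic(scores_pos, scores_neg) -> AucResult:
    """Tie-aware C-statistic with DeLong variance and 95% CI.

    ``auc = (#{pos > neg} + ½·#{pos = neg}) / (n_pos · n_neg)``; a class with
    a single member contributes zero to the variance (its placement
    covariance is not estimable).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    auc, v10, v01 = _placements(pos, neg)
    s10 = float(np.var(v10, ddof=1)) if v10.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if v01.size > 1 else 0.0
    variance = s10 / pos.size + s01 / neg.size
    se = float(np.sqrt(variance))
    lo = min(auc, max(0.0, auc - _Z975 * se))
    hi = max(auc, min(1.0, auc + _Z975 * se))
    return AucResult(auc, variance, lo, hi, int(pos.size), int(neg.size))


def auc_from_labels(scores, labels) -> AucResult:
    """Convenience wrapper: C-statistic from scores plus binary labels."""
    pos, neg = _split(scores, labels)
    return c_statistic(pos, neg)


def delong_difference_variance(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong AUC difference and its variance for paired scores.

    Returns ``(auc_a − auc_b, var)`` from the covariance of the two score
    sets' structural components on the same subjects.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must cover the same subjects")
    labels = np.asarray(labels).astype(bool)
    pos_a, neg_a = scores_a[labels], scores_a[~labels]
    pos_b, neg_b = scores_b[labels], scores_b[~labels]
    if pos_a.size == 0 or neg_a.size == 0:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _placements(pos_a, neg_a)
    auc_b, v10_b, v01_b = _placements(pos_b, neg_b)
    m, n = pos_a.size, neg_a.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n
    return auc_a - auc_b, float(var)


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong's test for two correlated AUCs measured on the same subjects.

    Returns ``(z, p)`` with a two-sided p-value from the standard normal.
    A degenerate comparison (zero variance of the difference) yields
    ``(0, 1)`` when the AUCs are equal and raises otherwise.
    """
    d, var = delong_difference_variance(scores_a, scores_b, labels)
    if var <= 0.0:
        if d == 0.0:
            return 0.0, 1.0
        raise ValueError("zero variance of the AUC difference with unequal AUCs")
    z = float(d / np.sqrt(var))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def roc_curve(scores, labels) -> RocCurve:
    """Stepwise ROC curve over all unique score cutpoints (higher = positive)."""
    pos, neg = _split(scores, labels)
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    thresholds = np.concatenate([np.unique(np.concatenate([pos, neg])), [np.inf]])
    # sens(t) = P(pos >= t), spec(t) = P(neg < t)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def select_threshold(curve: RocCurve, criterion: str = "youden") -> ThresholdChoice:
    """Youden-optimal cutpoint: maximize sensitivity + specificity − 1.

    Ties are broken toward the smallest threshold. With all scores identical
    the maximum J is 0 and the convention yields (sensitivity 1, specificity
    0) at the single observed value.
    """
    if criterion != "youden":
        raise ValueError("select_threshold only implements the 'youden' criterion")
    j = curve.sensitivity + curve.specificity - 1.0
    k = int(np.argmax(j))  # thresholds ascend -> first max is the smallest
    return ThresholdChoice(
        threshold=float(curve.thresholds[k]),
        sensitivity=float(curve.sensitivity[k]),
        specificity=float(curve.specificity[k]),
        criterion="youden",
    )


def threshold_performance(
    scores, labels, threshold: float, inclusive: bool = True
) -> ThresholdChoice:
    """Sensitivity/specificity of a fixed cutpoint (higher = positive).

    ``inclusive`` calls score == threshold positive (the ROC-curve
    convention); the published decision tree instead uses strict
    comparisons, see :mod:`modytree.classify_evaluate`.
    """
    pos, neg = _split(scores, labels)
    if inclusive:
        sens = float(np.mean(pos >= threshold))
        spec = float(np.mean(neg < threshold))
    else:
        sens = float(np.mean(pos > threshold))
        spec = float(np.mean(neg <= threshold))
    return ThresholdChoice(float(threshold), sens, spec, criterion="fixed")
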