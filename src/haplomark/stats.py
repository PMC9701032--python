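"""ROC/AUC machinery and inferential statistics for classifier evaluation.

AUC is computed through the Mann–Whitney identity with half credit for tied
scores, so it is invariant under strictly monotone score transforms.
Interval estimates come in two flavours: exact Clopper–Pearson binomial
intervals for sensitivity/specificity, and class-stratified bootstrap
percentile intervals for the AUC.  Two tests compare correlated AUCs: a
chi-square statistic T = (AUC_a - AUC_b)^2 / (s2_a + s2_b) with bootstrap
variances, referred to chi2(1); and the DeLong test from placement values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "clopper_pearson"
    variance: float | None = None


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    variance_a: float
    variance_b: float
    statistic: float
    p_value: float
    method: str


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes coded 0/1")
    return labels


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the rank statistic: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(scores, labels, cutoff: float | None = None) -> RocResult:
    """ROC curve and AUC; if ``cutoff`` is given, score >= cutoff is a call."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thr = roc_curve(labels, scores)
    res = RocResult(
        auc=mann_whitney_auc(scores, labels),
        fpr=fpr, tpr=tpr, thresholds=thr,
        n_pos=int(labels.sum()), n_neg=int((labels == 0).sum()),
    )
    if cutoff is not None:
        calls = scores >= cutoff
        res.cutoff = float(cutoff)
        res.sensitivity = float(calls[labels == 1].mean())
        res.specificity = float((~calls[labels == 0]).mean())
    return res


def youden_cutoff(scores, labels) -> float:
    """Cutoff maximising sensitivity + specificity - 1 on the given data."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    cut = thr[best]
    if np.isinf(cut):  # sklearn's sentinel above the max score
        cut = scores.max() + 1.0
    return float(cut)


def cutoff_at_specificity(scores, labels, specificity: float) -> float:
    """Smallest cutoff achieving at least the requested specificity."""
    labels = _check_binary(labels)
    neg = np.sort(np.asarray(scores, dtype=float)[labels == 0])
    k = int(np.ceil(specificity * neg.size))
    if k >= neg.size:
        return float(neg[-1] + np.finfo(float).eps + 1e-12)
    return float(np.nextafter(neg[k - 1], np.inf)) if k > 0 else float(neg[0])


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> IntervalEstimate:
    """Exact binomial interval from beta quantiles.

    The lower bound is exactly 0 when no successes are observed and the
    upper bound exactly 1 when all trials succeed.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes outside [0, trials]")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return IntervalEstimate(successes / trials, lower, upper, level, "clopper_pearson")


def _stratified_bootstrap_aucs(
    score_list: list[np.ndarray], labels: np.ndarray, reps: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Bootstrap AUCs for one or more paired score vectors.

    Resampling is stratified by class and the same resample indices apply to
    every score vector, which is what paired variance estimation needs.
    """
    labels = _check_binary(labels)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    m, n = pos_idx.size, neg_idx.size
    take_pos = pos_idx[rng.integers(0, m, size=(reps, m))]
    take_neg = neg_idx[rng.integers(0, n, size=(reps, n))]
    out = []
    for scores in score_list:
        scores = np.asarray(scores, dtype=float)
        combined = np.concatenate([scores[take_pos], scores[take_neg]], axis=1)
        ranks = sps.rankdata(combined, axis=1)
        aucs = (ranks[:, :m].sum(axis=1) - m * (m + 1) / 2) / (m * n)
        out.append(aucs)
    return out


def bootstrap_auc_ci(
    scores, labels, reps: int = 1000, level: float = 0.95, seed: int | None = None
) -> IntervalEstimate:
    """Class-stratified bootstrap percentile CI for the AUC.

    Also carries the bootstrap variance (``variance`` field) consumed by
    :func:`auc_compare_T`.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    (aucs,) = _stratified_bootstrap_aucs([np.asarray(scores)], np.asarray(labels), reps, rng)
    alpha = 1.0 - level
    lower, upper = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return IntervalEstimate(
        mann_whitney_auc(np.asarray(scores), np.asarray(labels)),
        float(lower), float(upper), level, "bootstrap_percentile",
        variance=float(aucs.var(ddof=1)),
    )


def auc_compare_T(a, b, labels, reps: int = 1000, seed: int | None = None) -> AucComparison:
    """Chi-square test for the difference of two correlated AUCs.

    T = (AUC_a - AUC_b)^2 / (s2_a + s2_b), with each variance estimated by a
    paired class-stratified bootstrap, is referred to the upper tail of
    chi2 with 1 degree of freedom.
    """
    labels = _check_binary(labels)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("score vectors must be paired on the same samples")
    rng = np.random.default_rng(seed)
    boot_a, boot_b = _stratified_bootstrap_aucs([a, b], labels, reps, rng)
    auc_a = mann_whitney_auc(a, labels)
    auc_b = mann_whitney_auc(b, labels)
    s2a = float(boot_a.var(ddof=1))
    s2b = float(boot_b.var(ddof=1))
    denom = s2a + s2b
    if denom == 0:
        if auc_a == auc_b:
            return AucComparison(auc_a, auc_b, s2a, s2b, 0.0, 1.0, "chi2_T")
        warnings.warn("zero combined bootstrap variance with unequal AUCs")
        return AucComparison(auc_a, auc_b, s2a, s2b, float("inf"), 0.0, "chi2_T")
    T = (auc_a - auc_b) ** 2 / denom
    return AucComparison(auc_a, auc_b, s2a, s2b, float(T),
                         float(sps.chi2.sf(T, df=1)), "chi2_T")


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    order = np.concatenate([pos, neg])
    ranks = sps.rankdata(order)
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    auc = (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (ranks[:m] - rank_pos) / n
    v01 = 1.0 - (ranks[m:] - rank_neg) / m
    return v10, v01, float(auc)


def delong_test(a, b, labels) -> AucComparison:
    """DeLong comparison of two correlated AUCs (two-sided normal p)."""
    labels = _check_binary(labels)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    v10a, v01a, auc_a = _placements(a, labels)
    v10b, v01b, auc_b = _placements(b, labels)
    m, n = v10a.size, v01a.size
    if m < 2 or n < 2:
        raise ValueError("need >= 2 samples per class for DeLong variance")
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        if auc_a == auc_b:
            return AucComparison(auc_a, auc_b, cov[0, 0], cov[1, 1], 0.0, 1.0, "delong")
        raise ValueError("degenerate DeLong variance with unequal AUCs")
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return AucComparison(auc_a, auc_b, float(cov[0, 0]), float(cov[1, 1]),
                         float(z * z), float(p), "delong")


def mcnemar_test(calls_a, calls_b, truth) -> float:
    """Exact binomial McNemar test on paired calls against a common truth.

    Discordant pairs are cases one method calls correctly and the other does
    not; the two-sided exact p comes from Binomial(b + c, 1/2).
    """
    calls_a = np.asarray(calls_a).astype(bool)
    calls_b = np.asarray(calls_b).astype(bool)
    truth = np.asarray(truth).astype(bool)
    correct_a = calls_a == truth
    correct_b = calls_b == truth
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    n = b + c
    if n == 0:
        return 1.0
    p = 2 * sps.binom.cdf(min(b, c), n, 0.5)
    if b == c:  # the central term would be double-counted
        p = 1.0
    return float(min(1.0, p))


def hypergeometric_enrichment(panel: set, reference: set, universe: int) -> float:
    """Upper-tail hypergeometric p for the observed panel/reference overlap."""
    k = len(panel & reference)
    K = len(reference)
    n = len(panel)
    if K > universe or n > universe:
        raise ValueError("set sizes exceed the universe")
    if k > min(K, n):
        raise ValueError("overlap exceeds set sizes")
    return float(sps.hypergeom.sf(k - 1, universe, K, n))
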