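"""The study's statistical toolkit.

Rank-sum comparison (exact enumeration for small tie-free samples, normal
approximation with tie and continuity correction otherwise), Pearson
correlation with a two-sided t-test, descriptive median/IQR summaries,
proportions, and ROC analysis with a DeLong 95% confidence interval and a
Youden-optimal operating point. Two-sided tests throughout, alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .signal_io import ValidationError

ALPHA = 0.05

#: exact rank-sum enumeration is used up to this pooled size (no ties)
EXACT_MAX_N = 12


@dataclass(frozen=True)
class CorrResult:
    r: float
    r_squared: float
    p_two_sided: float
    n: int


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    threshold: float
    direction: str  # "greater": higher score predicts the condition


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sample rank-sum (Mann-Whitney) test; returns (U of x, p).

    Uses exhaustive enumeration of group assignments on midranks when
    n_x + n_y <= 12 and the pooled sample is tie-free, with the two-sided
    p defined symmetrically as P(|T - E[T]| >= |t - E[T]|); otherwise the
    normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rank_sum_x = float(ranks[:nx].sum())
    u_x = rank_sum_x - nx * (nx + 1) / 2.0

    no_ties = len(np.unique(pooled)) == nx + ny
    if nx + ny <= EXACT_MAX_N:
        # enumerate every assignment of nx pooled ranks to group x; the
        # symmetric two-sided p also yields 1 for identical multisets
        mu = nx * (nx + ny + 1) / 2.0
        obs_dev = abs(rank_sum_x - mu)
        hits = 0
        total = 0
        for idx in combinations(range(nx + ny), nx):
            t = ranks[list(idx)].sum()
            if abs(t - mu) >= obs_dev - 1e-12:
                hits += 1
            total += 1
        return u_x, hits / total
    # normal approximation with tie correction and continuity correction
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pearson_test(x, y) -> CorrResult:
    """Pearson correlation with the two-sided t-test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrResult(r=r, r_squared=r * r, p_two_sided=float(res.pvalue), n=n)


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC analysis of a continuous score against a binary condition.

    AUC via the Mann-Whitney identity AUC = U/(n1*n0) with midrank ties.
    The score orientation is chosen so that AUC >= 0.5 and reported in
    ``direction``. The 95% CI is DeLong's by default, or a seeded
    stratified percentile bootstrap (``ci_method="bootstrap"``); the
    operating point maximizes Youden's J (sensitivity + specificity - 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValidationError("both classes must be present")
    if ci_method not in ("delong", "bootstrap"):
        raise ValidationError("ci_method must be 'delong' or 'bootstrap'")

    auc = _auc_mann_whitney(scores, labels)
    direction = "greater"
    if auc < 0.5:
        scores = -scores
        auc = _auc_mann_whitney(scores, labels)
        direction = "less"

    if ci_method == "delong":
        ci_low, ci_high = _delong_ci(scores, labels, auc)
    else:
        ci_low, ci_high = _bootstrap_ci(scores, labels, n_boot, seed)
    threshold, sens, spec = _youden_point(scores, labels)
    if direction == "less":
        threshold = -threshold
    return RocResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        sensitivity=sens,
        specificity=spec,
        threshold=threshold,
        direction=direction,
    )


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong variance of the AUC from placement values."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(1.0 - ALPHA / 2.0)
    return float(np.clip(auc - z * se, 0.0, 1.0)), float(np.clip(auc + z * se, 0.0, 1.0))


def _bootstrap_ci(
    scores: np.ndarray, labels: np.ndarray, n_boot: int, seed: int
) -> tuple[float, float]:
    """Stratified percentile bootstrap of the AUC (resampling within class)."""
    rng = np.random.default_rng(seed)
    pos = scores[labels]
    neg = scores[~labels]
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos, size=len(pos), replace=True)
        q = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([p, q])
        l = np.concatenate([np.ones(len(p), bool), np.zeros(len(q), bool)])
        aucs[i] = _auc_mann_whitney(s, l)
    lo, hi = np.percentile(aucs, [100 * ALPHA / 2, 100 * (1 - ALPHA / 2)])
    return float(lo), float(hi)


def _youden_point(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J, with its sensitivity/specificity.

    The rule is 'condition-positive iff score >= threshold'; candidate
    thresholds are the observed scores. Ties in J resolve to the highest
    threshold (fewest positives called)."""
    n1 = labels.sum()
    n0 = len(labels) - n1
    best = (-np.inf, np.nan, np.nan, np.nan)
    for thr in np.unique(scores)[::-1]:
        called = scores >= thr
        sens = float((called & labels).sum() / n1)
        spec = float((~called & ~labels).sum() / n0)
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    return float(best[1]), float(best[2]), float(best[3])


def proportion_pct(count: int, total: int) -> float:
    """100*count/total; rounding to display precision is the report's job."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= count <= total:
        raise ValidationError("count must lie in [0, total]")
    return 100.0 * count / total


def median_iqr(sample) -> tuple[float, float, float]:
    """Median and 25th-75th percentiles, linear-interpolation convention."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) == 0:
        raise ValidationError("empty sample")
    q25, q50, q75 = np.percentile(sample, [25.0, 50.0, 75.0])
    return float(q50), float(q25), float(q75)
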