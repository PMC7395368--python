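"""Independently coded naive oracles used by the tests.

These deliberately use explicit Python loops and textbook formulas, not
the package's vectorized implementations, so that equality checks are a
genuine dual-route verification.
"""

from __future__ import annotations

import math


def naive_pearson(x, y) -> float:
    n = len(x)
    sx = sum(x) / n
    sy = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - sx) * (yi - sy)
        sxx += (xi - sx) ** 2
        syy += (yi - sy) ** 2
    return sxy / math.sqrt(sxx * syy)


def _naive_flags(values, lo, hi, jump_sd, run_len):
    """Replicates the artifact gates with loops: range, jump, flat run."""
    n = len(values)
    flags = [False] * n
    for i, v in enumerate(values):
        if not math.isnan(v) and (v < lo or v > hi):
            flags[i] = True
    diffs = [values[i + 1] - values[i] for i in range(n - 1)]
    finite = sorted(d for d in diffs if not math.isnan(d))
    if len(finite) >= 10:
        med = _naive_median(finite)
        mad = _naive_median(sorted(abs(d - med) for d in finite))
        rsd = 1.4826 * mad
        if rsd > 0:
            for i, d in enumerate(diffs):
                if not math.isnan(d) and abs(d) > jump_sd * rsd:
                    flags[i + 1] = True
    if run_len >= 2:
        i = 0
        while i < n:
            j = i
            while (
                j + 1 < n
                and not math.isnan(values[j + 1])
                and not math.isnan(values[j])
                and values[j + 1] == values[j]
            ):
                j += 1
            # run of equal samples i..j; same-pair count is j - i
            if j - i >= run_len:
                for k in range(i, j + 1):
                    flags[k] = True
            i = j + 1
    return flags


def _naive_median(sorted_vals):
    n = len(sorted_vals)
    if n % 2:
        return sorted_vals[n // 2]
    return 0.5 * (sorted_vals[n // 2 - 1] + sorted_vals[n // 2])


def naive_window_means(values, rate, window_s, overlap_frac, max_missing_frac):
    """Window means by explicit summation; NaN where too much is missing."""
    n_per = int(round(window_s * rate))
    n_step = window_s * (1.0 - overlap_frac) * rate
    means = []
    k = 0
    while True:
        i0 = int(round(k * n_step))
        i1 = i0 + n_per
        if i1 > len(values):
            break
        total = 0.0
        count = 0
        missing = 0
        for v in values[i0:i1]:
            if math.isnan(v):
                missing += 1
            else:
                total += v
                count += 1
        if missing / n_per > max_missing_frac or count == 0:
            means.append(math.nan)
        else:
            means.append(total / count)
        k += 1
    return means


def naive_mxa(abp_values, fv_values, rate, config) -> float:
    """The full chain (artifacts -> window means -> drop pairs -> Pearson)
    with explicit loops, for equal-rate, already-aligned signals."""
    rules = config.artifact_rules
    run_len = int(round(rules.flat_run_s * rate))
    a_flags = _naive_flags(list(abp_values), *rules.abp_range, rules.jump_sd, run_len)
    f_flags = _naive_flags(list(fv_values), *rules.fv_range, rules.jump_sd, run_len)
    a = [math.nan if fl else v for v, fl in zip(abp_values, a_flags)]
    f = [math.nan if fl else v for v, fl in zip(fv_values, f_flags)]
    am = naive_window_means(a, rate, config.window_s, config.overlap_frac, config.max_missing_frac)
    fm = naive_window_means(f, rate, config.window_s, config.overlap_frac, config.max_missing_frac)
    xs, ys = [], []
    for x, y in zip(am, fm):
        if not math.isnan(x) and not math.isnan(y):
            xs.append(x)
            ys.append(y)
    return naive_pearson(xs, ys)


def naive_percentile(sample, q) -> float:
    """Linear-interpolation percentile between order statistics."""
    s = sorted(sample)
    if len(s) == 1:
        return s[0]
    pos = q / 100.0 * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def naive_trapezoid_auc(scores, labels) -> float:
    """AUC as the trapezoidal integral of the empirical ROC curve."""
    thresholds = sorted(set(scores), reverse=True)
    n1 = sum(labels)
    n0 = len(labels) - n1
    pts = [(0.0, 0.0)]
    for thr in thresholds:
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= thr)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s >= thr)
        pts.append((fp / n0, tp / n1))
    pts.append((1.0, 1.0))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return auc


def naive_mannwhitney_u(x, y) -> float:
    """U statistic of x by direct pair counting with half-credit ties."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def naive_rank_sum_exact_p(x, y):
    """Two-sided exact rank-sum p by enumerating group assignments of the
    pooled sample (independent of the package's combination order)."""
    from itertools import combinations

    pooled = sorted(list(x) + list(y))
    # midranks
    ranks = []
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[j + 1] == pooled[i]:
            j += 1
        for _ in range(i, j + 1):
            ranks.append((i + j) / 2.0 + 1.0)
        i = j + 1
    # observed rank sum of x, using the pooled order mapping
    order = sorted(range(len(pooled)), key=lambda k: pooled[k])
    # assign observed ranks by matching values greedily
    vals = list(x) + list(y)
    remaining = list(range(len(pooled)))
    obs = 0.0
    for k, v in enumerate(vals):
        for idx in remaining:
            if pooled[idx] == v:
                if k < len(x):
                    obs += ranks[idx]
                remaining.remove(idx)
                break
    nx = len(x)
    n = len(pooled)
    mu = nx * (n + 1) / 2.0
    dev = abs(obs - mu)
    hits = total = 0
    for comb in combinations(range(n), nx):
        t = sum(ranks[i] for i in comb)
        total += 1
        if abs(t - mu) >= dev - 1e-12:
            hits += 1
    return hits / total
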