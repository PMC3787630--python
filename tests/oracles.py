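"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own computational paths: residual
regressions go through statsmodels OLS, rankings and aligner selections are
plain-Python loops over single-pair calls, and AUC comes from the
Mann-Whitney U statistic.
"""

from __future__ import annotations

import math

import numpy as np
import statsmodels.api as sm

from peakalign import (
    DistanceMeasureSpec,
    PeakList,
    SimilarityMeasureSpec,
    UndefinedSimilarityError,
    cosine_similarity,
    pearson_similarity,
    rt_distance,
    spearman_similarity,
    two_step_similarity,
)


def ols_residual(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of v regressed (with intercept) on the rows of Z."""
    design = sm.add_constant(np.asarray(Z, dtype=float).T, has_constant="add")
    return sm.OLS(np.asarray(v, dtype=float), design).fit().resid


def partial_oracle(x, yi, Z) -> float:
    """Two-regression residual-correlation form of the partial correlation."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.size == 0:
        return float(np.corrcoef(x, yi)[0, 1])
    rx = ols_residual(x, Z)
    ry = ols_residual(yi, Z)
    return float(np.corrcoef(rx, ry)[0, 1])


def part_oracle(x, yi, Z) -> float:
    """One-regression (semipartial) form: raw x vs residual of yi."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.size == 0:
        return float(np.corrcoef(x, yi)[0, 1])
    ry = ols_residual(yi, Z)
    return float(np.corrcoef(x, ry)[0, 1])


def conditioning_set_oracle(x, reference: PeakList, i: int, q: int) -> tuple:
    """Full-sort ranking of Y^(i) by Pearson correlation with x."""
    scored = []
    for j, peak in enumerate(reference):
        if j == i:
            continue
        try:
            r = pearson_similarity(x, peak.spectrum)
        except UndefinedSimilarityError:
            r = -math.inf
        scored.append((-r, j))
    scored.sort()
    return tuple(j for _, j in scored[:q])


def pair_score(t_peak, reference: PeakList, i: int, spec: SimilarityMeasureSpec):
    """Single-pair similarity under any measure spec; None when undefined."""
    fns = {
        "cosine": cosine_similarity,
        "pearson": pearson_similarity,
        "spearman": spearman_similarity,
    }
    try:
        if spec.kind in fns:
            return fns[spec.kind](t_peak.spectrum, reference[i].spectrum)
        return two_step_similarity(t_peak.spectrum, reference, i, spec)
    except UndefinedSimilarityError:
        return None


def _tie_select_max(candidates, scores, tie_dist):
    best = max(scores[i] for i in candidates)
    tied = [i for i in candidates if scores[i] == best]
    return min(tied, key=lambda i: (tie_dist[i], i))


def brute_pad(T, R, dspec):
    out = []
    for j, t in enumerate(T):
        d = [rt_distance(t, r, dspec) for r in R]
        i = min(range(len(R)), key=lambda i: (d[i], i))
        out.append((j, i))
    return out


def brute_pas(T, R, spec, tie_dspec=DistanceMeasureSpec("euclidean")):
    out = []
    for j, t in enumerate(T):
        scores = {i: pair_score(t, R, i, spec) for i in range(len(R))}
        defined = [i for i, v in scores.items() if v is not None]
        if not defined:
            continue
        tie = [rt_distance(t, r, tie_dspec) for r in R]
        out.append((j, _tie_select_max(defined, scores, tie)))
    return out


def brute_dw_pas(T, R, dspec, k, spec):
    out = []
    for j, t in enumerate(T):
        d = [rt_distance(t, r, dspec) for r in R]
        window = sorted(range(len(R)), key=lambda i: (d[i], i))[:k]
        scores = {i: pair_score(t, R, i, spec) for i in window}
        defined = [i for i in window if scores[i] is not None]
        if not defined:
            continue
        out.append((j, _tie_select_max(defined, scores, d)))
    return out


def brute_sw_pad(T, R, spec, rho, dspec):
    out = []
    for j, t in enumerate(T):
        window = []
        for i in range(len(R)):
            v = pair_score(t, R, i, spec)
            if v is not None and v >= rho:
                window.append(i)
        if not window:
            continue
        d = [rt_distance(t, r, dspec) for r in R]
        out.append((j, min(window, key=lambda i: (d[i], i))))
    return out


def brute_pam(T, R, w, dspec, spec):
    out = []
    for j, t in enumerate(T):
        d = [rt_distance(t, r, dspec) for r in R]
        scores = {}
        for i in range(len(R)):
            if w == 1.0:
                scores[i] = 1.0 / (1.0 + d[i])
            else:
                s = pair_score(t, R, i, spec)
                if s is None:
                    continue
                scores[i] = w / (1.0 + d[i]) + (1.0 - w) * s
        if not scores:
            continue
        out.append((j, _tie_select_max(list(scores), scores, d)))
    return out


def mann_whitney_auc(scores, labels) -> float:
    from scipy.stats import mannwhitneyu

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))
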