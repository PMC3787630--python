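"""Alignment performance evaluation: confusion counts, TPR/FPR/PPV/F1, ROC/AUC.

With s true peak pairs, u matched pairs, and TP of the matches correct:

    FP = u - TP,   FN = s - TP,   TN = m·n - s - FP,
    TPR = TP/s,    FPR = (u - TP)/(m·n - s),
    PPV = TP/u,    F1 = 2·TP/(s + u).

Two ROC constructions are provided.  :func:`roc_curve` is the standard
empirical ROC over a set of scored, labeled candidate pairs (its trapezoidal
AUC equals the Mann–Whitney rank statistic on ties-free scores).
:func:`alignment_roc` thresholds an aligner's own match scores and uses the
alignment denominators s and m·n - s, so the curve describes how the
matched set degrades as the acceptance cut-off rises; when no match
survives a cut-off, (FPR, TPR) = (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignmentResult
from .model import PeakList, TruePairSet
from .similarity import SimilarityMeasureSpec, similarity_matrix

__all__ = [
    "EvaluationReport",
    "ROCCurve",
    "count_outcomes",
    "compute_metrics",
    "evaluate_alignment",
    "roc_curve",
    "alignment_roc",
    "score_distributions",
    "overlap_coefficient",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and derived rates for one alignment run.

    PPV and F1 are NaN when u = 0 (no matched pairs).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    tpr: float
    fpr: float
    ppv: float
    f1: float
    m: int
    n: int
    s: int
    u: int

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "TPR": self.tpr, "FPR": self.fpr, "PPV": self.ppv, "F1": self.f1,
            "m": self.m, "n": self.n, "s": self.s, "u": self.u,
        }


@dataclass(frozen=True)
class ROCCurve:
    """Cut-offs (descending), one (FPR, TPR) point per cut-off, and AUC.

    ``auc`` is the trapezoidal integral of the points anchored at (0, 0)
    and (1, 1).
    """

    cutoffs: np.ndarray
    points: np.ndarray  # shape (len(cutoffs), 2): columns FPR, TPR
    auc: float

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


def count_outcomes(
    result: AlignmentResult, truth: TruePairSet, m: int, n: int
) -> dict:
    """TP/FP/FN/TN counts for matches against ground truth.

    Matches are (target, reference) pairs; truth pairs are (reference,
    target).  Raises on out-of-range indices.
    """
    if m < 1 or n < 1:
        raise ValueError("peak list sizes m, n must be >= 1")
    for r, t in truth.pairs:
        if r >= m or t >= n:
            raise ValueError(f"true pair ({r},{t}) outside {m}x{n} lists")
    for t, r, _ in result.matches:
        if not (0 <= t < n and 0 <= r < m):
            raise ValueError(f"match ({t},{r}) outside {m}x{n} lists")
    s = truth.s
    u = result.u
    tp = sum((r, t) in truth.pairs for t, r, _ in result.matches)
    fp = u - tp
    return {
        "TP": tp, "FP": fp, "FN": s - tp, "TN": m * n - s - fp,
        "m": m, "n": n, "s": s, "u": u,
    }


def compute_metrics(counts: dict) -> EvaluationReport:
    """Derive TPR/FPR/PPV/F1 from confusion counts.

    Requires s > 0; with u = 0 the precision-type metrics are NaN while
    TPR/FPR are still computed.
    """
    tp, s, u, m, n = (counts[k] for k in ("TP", "s", "u", "m", "n"))
    if s <= 0:
        raise ValueError("metrics require at least one true pair (s > 0)")
    denom_neg = m * n - s
    tpr = tp / s
    fpr = (u - tp) / denom_neg if denom_neg > 0 else float("nan")
    ppv = tp / u if u > 0 else float("nan")
    f1 = 2.0 * tp / (s + u) if u > 0 else float("nan")
    return EvaluationReport(
        tp=tp, fp=counts["FP"], fn=counts["FN"], tn=counts["TN"],
        tpr=tpr, fpr=fpr, ppv=ppv, f1=f1, m=m, n=n, s=s, u=u,
    )


def evaluate_alignment(
    result: AlignmentResult, truth: TruePairSet, m: int, n: int
) -> EvaluationReport:
    """Convenience: count outcomes then compute metrics."""
    return compute_metrics(count_outcomes(result, truth, m, n))


def _anchored_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    xs = np.concatenate([[0.0], fpr, [1.0]])
    ys = np.concatenate([[0.0], tpr, [1.0]])
    order = np.argsort(xs, kind="stable")
    return float(np.trapezoid(ys[order], xs[order]))


def roc_curve(
    scores, labels, cutoffs: np.ndarray | None = None
) -> ROCCurve:
    """Empirical ROC over scored candidate pairs with binary truth labels.

    At each cut-off c, pairs with score >= c are called positive; TPR and
    FPR are computed against the labeled positives/negatives of the input
    set.  Cut-offs default to the sorted unique observed scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    pos = int(labels.sum())
    neg = int(labels.size - pos)
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires at least one true and one false pair")
    if cutoffs is None:
        cutoffs = np.unique(scores)[::-1]
    else:
        cutoffs = np.sort(np.asarray(cutoffs, dtype=np.float64))[::-1]
    tprs = np.empty(cutoffs.size)
    fprs = np.empty(cutoffs.size)
    for idx, c in enumerate(cutoffs):
        sel = scores >= c
        tprs[idx] = labels[sel].sum() / pos
        fprs[idx] = (~labels[sel]).sum() / neg
    return ROCCurve(
        cutoffs=cutoffs,
        points=np.column_stack([fprs, tprs]),
        auc=_anchored_auc(fprs, tprs),
    )


def alignment_roc(
    result: AlignmentResult,
    truth: TruePairSet,
    m: int,
    n: int,
    cutoffs: np.ndarray | None = None,
) -> ROCCurve:
    """ROC from an aligner's match scores, thresholded at each cut-off.

    Keeping only matches with score >= c gives u(c) pairs of which TP(c)
    are true; then TPR = TP(c)/s and FPR = (u(c) - TP(c))/(m·n - s).
    """
    if truth.s == 0 or m * n - truth.s == 0:
        raise ValueError("degenerate truth set for ROC")
    scores = np.array([sc for _, _, sc in result.matches], dtype=np.float64)
    is_true = np.array(
        [(r, t) in truth.pairs for t, r, _ in result.matches], dtype=bool
    )
    if cutoffs is None:
        cutoffs = np.unique(scores)[::-1]
    else:
        cutoffs = np.sort(np.asarray(cutoffs, dtype=np.float64))[::-1]
    s = truth.s
    neg = m * n - s
    tprs = np.empty(cutoffs.size)
    fprs = np.empty(cutoffs.size)
    for idx, c in enumerate(cutoffs):
        sel = scores >= c
        tp = int(is_true[sel].sum())
        u = int(sel.sum())
        tprs[idx] = tp / s
        fprs[idx] = (u - tp) / neg
    return ROCCurve(
        cutoffs=cutoffs,
        points=np.column_stack([fprs, tprs]),
        auc=_anchored_auc(fprs, tprs),
    )


def score_distributions(
    R: PeakList, T: PeakList, truth: TruePairSet, spec: SimilarityMeasureSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Similarity scores over true pairs vs over all other cross pairs.

    Returns (same-peak scores, different-peak scores) with sizes s and
    m·n - s; undefined scores appear as NaN.  Used for the separation
    diagnostic: an informative measure concentrates same-peak scores near 1
    and different-peak scores near 0 (cosine) or below.
    """
    S = similarity_matrix(T, R, spec).values
    n, m = S.shape
    mask = np.zeros((n, m), dtype=bool)
    for r, t in truth.pairs:
        mask[t, r] = True
    return S[mask], S[~mask]


def overlap_coefficient(a, b, bins: int = 64) -> float:
    """Histogram overlap of two score samples (0 = disjoint, 1 = identical).

    NaNs are dropped; both samples share one binning over the pooled range.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("need nonempty, finite score samples")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(pa / a.size, pb / b.size).sum())
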