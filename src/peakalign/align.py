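"""Peak-matching alignment procedures.

Five aligners, all per-target selections over the reference list:

* PAD    — nearest reference by retention-time distance alone.
* PAS    — most spectrally similar reference alone.
* DW-PAS — most similar reference within the k-nearest-distance window.
* SW-PAD — nearest reference among those with similarity >= rho.
* PAM    — reference maximizing the mixture score
           M = w/(1 + D) + (1 - w)·S, blending a distance-decreasing term
           with spectral similarity via weight w in [0, 1].

Matching is per-target argmax/argmin: a reference peak may be matched by
several targets (no bijection is enforced; an optional one-to-one
assignment mode is available via :func:`align`).  Score ties break by
smaller rt distance, then lower reference index.  Targets whose every
candidate score is undefined are left unmatched, so the number of matched
pairs u may be smaller than n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .distance import DistanceMeasureSpec, distance_matrix
from .model import PeakList
from .similarity import SimilarityMatrix, SimilarityMeasureSpec, similarity_matrix

__all__ = [
    "AlignmentResult",
    "mixture_score",
    "align_pad",
    "align_pas",
    "align_dw_pas",
    "align_sw_pad",
    "align_pam",
    "align",
    "METHODS",
]

METHODS = ("pad", "pas", "dw_pas", "sw_pad", "pam")


@dataclass(frozen=True)
class AlignmentResult:
    """Matched (target index, reference index, score) triples plus provenance."""

    matches: tuple[tuple[int, int, float], ...]
    method: str
    params: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        targets = [t for t, _, _ in self.matches]
        if len(set(targets)) != len(targets):
            raise ValueError("a target index appears in more than one match")

    @property
    def u(self) -> int:
        """Number of matched pairs."""
        return len(self.matches)

    def pairs(self) -> set[tuple[int, int]]:
        """Matched pairs as (target index, reference index)."""
        return {(t, r) for t, r, _ in self.matches}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.matches), columns=["target_index", "ref_index", "score"]
        )


def mixture_score(d: float, s: float, w: float) -> float:
    """Mixture similarity M = w/(1+d) + (1-w)*s for distance d and similarity s."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("mixture weight w must lie in [0, 1]")
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return w / (1.0 + d) + (1.0 - w) * s


def _select_min_distance(drow: np.ndarray, allowed: np.ndarray | None = None):
    """Index of minimal distance among allowed candidates (lower index on ties)."""
    if allowed is None:
        cand = np.arange(drow.size)
    else:
        cand = np.asarray(allowed, dtype=int)
        if cand.size == 0:
            return None
    best = drow[cand].min()
    return int(cand[np.flatnonzero(drow[cand] == best)[0]])


def _select_max_score(scores: np.ndarray, tie_dist: np.ndarray):
    """Index of maximal defined score; ties break by smaller tie_dist, then index."""
    valid = ~np.isnan(scores)
    if not valid.any():
        return None
    best = np.max(scores[valid])
    cand = np.flatnonzero(valid & (scores == best))
    if cand.size > 1:
        cand = cand[np.lexsort((cand, tie_dist[cand]))]
    return int(cand[0])


def align_pad(
    T: PeakList,
    R: PeakList,
    dspec: DistanceMeasureSpec = DistanceMeasureSpec("euclidean"),
    *,
    dist: np.ndarray | None = None,
) -> AlignmentResult:
    """Match each target to the reference at minimal rt distance; score = -D."""
    D = distance_matrix(T, R, dspec) if dist is None else dist
    matches = []
    for j in range(len(T)):
        i = _select_min_distance(D[j])
        matches.append((j, i, -float(D[j, i])))
    return AlignmentResult(
        tuple(matches), "pad", {"distance": dspec.kind}
    )


def align_pas(
    T: PeakList,
    R: PeakList,
    sspec: SimilarityMeasureSpec,
    *,
    sim: SimilarityMatrix | None = None,
    tie_dspec: DistanceMeasureSpec = DistanceMeasureSpec("euclidean"),
) -> AlignmentResult:
    """Match each target to the most spectrally similar reference."""
    S = (sim or similarity_matrix(T, R, sspec)).values
    Dtie = distance_matrix(T, R, tie_dspec)
    matches = []
    for j in range(len(T)):
        i = _select_max_score(S[j], Dtie[j])
        if i is not None:
            matches.append((j, i, float(S[j, i])))
    return AlignmentResult(
        tuple(matches), "pas", {"measure": sspec.describe()}
    )


def align_dw_pas(
    T: PeakList,
    R: PeakList,
    dspec: DistanceMeasureSpec,
    k: int,
    sspec: SimilarityMeasureSpec,
    *,
    sim: SimilarityMatrix | None = None,
    dist: np.ndarray | None = None,
) -> AlignmentResult:
    """Similarity-maximal reference within the k-nearest-distance window."""
    if k < 1:
        raise ValueError("window rank k must be >= 1")
    S = (sim or similarity_matrix(T, R, sspec)).values
    D = distance_matrix(T, R, dspec) if dist is None else dist
    m = len(R)
    matches = []
    for j in range(len(T)):
        window = np.argsort(D[j], kind="stable")[: min(k, m)]
        masked = np.full(m, np.nan)
        masked[window] = S[j, window]
        i = _select_max_score(masked, D[j])
        if i is not None:
            matches.append((j, i, float(S[j, i])))
    return AlignmentResult(
        tuple(matches),
        "dw_pas",
        {"distance": dspec.kind, "k": k, "measure": sspec.describe()},
    )


def align_sw_pad(
    T: PeakList,
    R: PeakList,
    sspec: SimilarityMeasureSpec,
    rho: float,
    dspec: DistanceMeasureSpec,
    *,
    sim: SimilarityMatrix | None = None,
    dist: np.ndarray | None = None,
) -> AlignmentResult:
    """Distance-minimal reference among those with similarity >= rho.

    Targets whose window is empty (no reference reaches the cut-off, or all
    scores undefined) are left unmatched.  The recorded score is -D of the
    selected pair (the selection quantity).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("similarity cut-off rho must lie in [0, 1]")
    S = (sim or similarity_matrix(T, R, sspec)).values
    D = distance_matrix(T, R, dspec) if dist is None else dist
    matches = []
    for j in range(len(T)):
        with np.errstate(invalid="ignore"):
            window = np.flatnonzero(S[j] >= rho)  # NaN fails the cut-off
        i = _select_min_distance(D[j], window)
        if i is not None:
            matches.append((j, i, -float(D[j, i])))
    return AlignmentResult(
        tuple(matches),
        "sw_pad",
        {"measure": sspec.describe(), "rho": rho, "distance": dspec.kind},
    )


def align_pam(
    T: PeakList,
    R: PeakList,
    w: float,
    dspec: DistanceMeasureSpec,
    sspec: SimilarityMeasureSpec,
    *,
    sim: SimilarityMatrix | None = None,
    dist: np.ndarray | None = None,
) -> AlignmentResult:
    """Reference maximizing the mixture score M = w/(1+D) + (1-w)·S.

    At w = 1 the similarity term vanishes and the method reduces to a
    monotone transform of PAD; undefined similarities then no longer
    disqualify a candidate.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("mixture weight w must lie in [0, 1]")
    D = distance_matrix(T, R, dspec) if dist is None else dist
    if w == 1.0:
        M = 1.0 / (1.0 + D)
    else:
        S = (sim or similarity_matrix(T, R, sspec)).values
        M = w / (1.0 + D) + (1.0 - w) * S  # NaN similarity propagates
    matches = []
    for j in range(len(T)):
        i = _select_max_score(M[j], D[j])
        if i is not None:
            matches.append((j, i, float(M[j, i])))
    return AlignmentResult(
        tuple(matches),
        "pam",
        {"w": w, "distance": dspec.kind, "measure": sspec.describe()},
    )


def _one_to_one(score: np.ndarray, method: str, params: dict) -> AlignmentResult:
    """Globally optimal one-to-one assignment over a score matrix (NaN = forbidden)."""
    from scipy.optimize import linear_sum_assignment

    filled = np.where(np.isnan(score), -1e300, score)
    rows, cols = linear_sum_assignment(filled, maximize=True)
    matches = tuple(
        (int(j), int(i), float(score[j, i]))
        for j, i in zip(rows, cols)
        if not np.isnan(score[j, i])
    )
    return AlignmentResult(matches, method, {**params, "one_to_one": True})


def align(
    method: str,
    T: PeakList,
    R: PeakList,
    *,
    sspec: SimilarityMeasureSpec | None = None,
    dspec: DistanceMeasureSpec | None = None,
    k: int | None = None,
    rho: float | None = None,
    w: float | None = None,
    one_to_one: bool = False,
) -> AlignmentResult:
    """Dispatch to an aligner by name; optionally enforce a bijection.

    In one-to-one mode the per-target selection scores form a score matrix
    (window exclusions become forbidden entries) and a maximum-score
    assignment is computed instead of independent per-target argmaxes.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    dspec = dspec or DistanceMeasureSpec("euclidean")
    if method == "pad":
        D = distance_matrix(T, R, dspec)
        if one_to_one:
            return _one_to_one(-D, "pad", {"distance": dspec.kind})
        return align_pad(T, R, dspec, dist=D)
    if sspec is None:
        raise ValueError(f"method {method!r} requires a similarity measure")
    if method == "pas":
        if one_to_one:
            S = similarity_matrix(T, R, sspec).values
            return _one_to_one(S, "pas", {"measure": sspec.describe()})
        return align_pas(T, R, sspec)
    if method == "dw_pas":
        if k is None:
            raise ValueError("dw_pas requires window rank k")
        if one_to_one:
            S = similarity_matrix(T, R, sspec).values
            D = distance_matrix(T, R, dspec)
            masked = np.full_like(S, np.nan)
            for j in range(len(T)):
                win = np.argsort(D[j], kind="stable")[: min(k, len(R))]
                masked[j, win] = S[j, win]
            return _one_to_one(
                masked, "dw_pas",
                {"distance": dspec.kind, "k": k, "measure": sspec.describe()},
            )
        return align_dw_pas(T, R, dspec, k, sspec)
    if method == "sw_pad":
        if rho is None:
            raise ValueError("sw_pad requires similarity cut-off rho")
        if one_to_one:
            S = similarity_matrix(T, R, sspec).values
            D = distance_matrix(T, R, dspec)
            with np.errstate(invalid="ignore"):
                masked = np.where(S >= rho, -D, np.nan)
            return _one_to_one(
                masked, "sw_pad",
                {"measure": sspec.describe(), "rho": rho, "distance": dspec.kind},
            )
        return align_sw_pad(T, R, sspec, rho, dspec)
    # pam
    if w is None:
        raise ValueError("pam requires mixture weight w")
    if one_to_one:
        D = distance_matrix(T, R, dspec)
        if w == 1.0:
            M = 1.0 / (1.0 + D)
        else:
            M = w / (1.0 + D) + (1.0 - w) * similarity_matrix(T, R, sspec).values
        return _one_to_one(
            M, "pam", {"w": w, "distance": dspec.kind, "measure": sspec.describe()}
        )
    return align_pam(T, R, w, dspec, sspec)
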