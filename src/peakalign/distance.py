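"""Retention-time distance measures and rank-based distance windows.

Distances act on the 2-D retention-time coordinates (rt1, rt2) of a peak
pair: Euclidean, Maximum (Chebyshev), Manhattan, and Canberra.  Canberra
normalizes each dimension by the sum of absolute coordinates, so it is
insensitive to the very different scales of the two chromatographic
dimensions (minutes-scale rt1 vs seconds-scale rt2); a zero-denominator
term contributes 0.  Retention times are not standardized beforehand
(raw seconds); Canberra is self-normalizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Peak, PeakList

__all__ = [
    "DISTANCE_KINDS",
    "DistanceMeasureSpec",
    "rt_distance",
    "distance_matrix",
    "distance_rank_window",
]

DISTANCE_KINDS = ("euclidean", "maximum", "manhattan", "canberra")


@dataclass(frozen=True)
class DistanceMeasureSpec:
    """Retention-time distance selection."""

    kind: str = "euclidean"

    def __post_init__(self) -> None:
        if self.kind not in DISTANCE_KINDS:
            raise ValueError(
                f"unknown distance {self.kind!r}; expected one of {DISTANCE_KINDS}"
            )


def _pair_distance(
    a1: np.ndarray, a2: np.ndarray, b1: np.ndarray, b2: np.ndarray, kind: str
) -> np.ndarray:
    d1 = np.abs(a1 - b1)
    d2 = np.abs(a2 - b2)
    if kind == "euclidean":
        return np.hypot(d1, d2)
    if kind == "maximum":
        return np.maximum(d1, d2)
    if kind == "manhattan":
        return d1 + d2
    # canberra: per-dimension |delta| / (|a| + |b|); 0/0 terms contribute 0
    den1 = np.abs(a1) + np.abs(b1)
    den2 = np.abs(a2) + np.abs(b2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(den1 > 0.0, d1 / den1, 0.0)
        t2 = np.where(den2 > 0.0, d2 / den2, 0.0)
    return t1 + t2


def rt_distance(a: Peak, b: Peak, spec: DistanceMeasureSpec) -> float:
    """Distance between the retention-time coordinates of two peaks."""
    return float(
        _pair_distance(
            np.float64(a.rt1),
            np.float64(a.rt2),
            np.float64(b.rt1),
            np.float64(b.rt2),
            spec.kind,
        )
    )


def distance_matrix(
    target: PeakList, reference: PeakList, spec: DistanceMeasureSpec
) -> np.ndarray:
    """(n, m) matrix of rt distances, entry (j, i) = D(target_j, reference_i)."""
    t = target.rts()
    r = reference.rts()
    return _pair_distance(
        t[:, 0, None], t[:, 1, None], r[None, :, 0], r[None, :, 1], spec.kind
    )


def distance_rank_window(
    t: Peak, reference: PeakList, spec: DistanceMeasureSpec, k: int
) -> tuple[int, ...]:
    """Indices of the k reference peaks nearest to ``t`` under ``spec``.

    Ties at the window boundary break toward the lower reference index;
    with k >= m every index is returned.  Returned in ascending-distance
    order.
    """
    if k < 1:
        raise ValueError("window rank k must be >= 1")
    r = reference.rts()
    d = _pair_distance(
        np.float64(t.rt1), np.float64(t.rt2), r[:, 0], r[:, 1], spec.kind
    )
    order = np.argsort(d, kind="stable")
    return tuple(int(i) for i in order[: min(k, len(reference))])
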