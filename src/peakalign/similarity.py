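"""Mass-spectral similarity measures for peak matching.

Five measures are provided: cosine (dot product), Pearson, Spearman,
partial correlation and part (semipartial) correlation.  The partial
correlation between a target spectrum X and reference spectrum Y_i,
conditioning on the remaining reference spectra Y^(i), is the Pearson
correlation of the residuals of X and Y_i after least-squares regression
(with intercept) on Y^(i); the part correlation correlates raw X with the
residual of Y_i only, and is therefore asymmetric in (X, Y_i).

When reference peaks outnumber m/z channels the full conditioning design is
singular.  The two-step variants avoid this by conditioning only on the q
reference spectra most Pearson-correlated with X (rank computed in
descending order over Y^(i), i.e. peak i itself does not consume a rank
slot); q is typically drawn from {3, 5, 7, 10, 15, 20, 30, 50, 70, 100}.

Here each peak plays the role of a random variable and the intensities at
the g m/z channels are its observations, so the correlations are sample
correlations over channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .model import MassSpectrum, PeakList

__all__ = [
    "UndefinedSimilarityError",
    "SimilarityMeasureSpec",
    "SimilarityMatrix",
    "MEASURE_KINDS",
    "cosine_similarity",
    "pearson_similarity",
    "spearman_similarity",
    "partial_similarity",
    "part_similarity",
    "two_step_conditioning_set",
    "two_step_similarity",
    "similarity_matrix",
]

MEASURE_KINDS = ("cosine", "pearson", "spearman", "partial", "part")

# A residual whose spread is below this fraction of the original spectrum's
# spread is treated as numerically zero (the conditioning set explains the
# spectrum, e.g. duplicate peaks): the score is undefined rather than noise.
_RESIDUAL_REL_TOL = 1e-10


class UndefinedSimilarityError(ValueError):
    """Similarity score is undefined (zero norm, constant or fully explained)."""


@dataclass(frozen=True)
class SimilarityMeasureSpec:
    """A similarity measure selection: kind plus optional two-step rank q.

    ``q`` applies only to ``partial``/``part``; when absent, those measures
    condition on the full set of other reference spectra.
    """

    kind: str
    q: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in MEASURE_KINDS:
            raise ValueError(
                f"unknown measure {self.kind!r}; expected one of {MEASURE_KINDS}"
            )
        if self.q is not None:
            if self.kind not in ("partial", "part"):
                raise ValueError("q applies only to partial/part measures")
            if int(self.q) < 2:
                raise ValueError("two-step rank q must be >= 2")
            object.__setattr__(self, "q", int(self.q))

    @property
    def conditioned(self) -> bool:
        return self.kind in ("partial", "part")

    def describe(self) -> str:
        return self.kind if self.q is None else f"{self.kind}(q={self.q})"


@dataclass(frozen=True)
class SimilarityMatrix:
    """n×m matrix of scores; entry (j, i) = S(target_j, reference_i).

    Undefined scores are stored as NaN.
    """

    values: np.ndarray
    measure: SimilarityMeasureSpec

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def entry(self, j: int, i: int) -> float:
        return float(self.values[j, i])


def _vec(x) -> np.ndarray:
    if isinstance(x, MassSpectrum):
        return x.intensities
    v = np.asarray(x, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("spectrum must be a 1-D vector")
    return v


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a0 = a - a.mean()
    b0 = b - b.mean()
    na = np.linalg.norm(a0)
    nb = np.linalg.norm(b0)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("constant spectrum: correlation undefined")
    return float(a0 @ b0 / (na * nb))


def cosine_similarity(x, y) -> float:
    """Cosine of the angle between two intensity vectors (dot product score)."""
    a, b = _vec(x), _vec(y)
    if a.size != b.size:
        raise ValueError("spectra must share one m/z grid")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("zero-norm spectrum: cosine undefined")
    return float(a @ b / (na * nb))


def pearson_similarity(x, y) -> float:
    """Pearson correlation over m/z channels."""
    a, b = _vec(x), _vec(y)
    if a.size != b.size:
        raise ValueError("spectra must share one m/z grid")
    return _pearson(a, b)


def spearman_similarity(x, y) -> float:
    """Pearson correlation of channel ranks (average ranks on ties)."""
    a, b = _vec(x), _vec(y)
    if a.size != b.size:
        raise ValueError("spectra must share one m/z grid")
    return _pearson(rankdata(a), rankdata(b))


def _conditioning_matrix(conditioning) -> np.ndarray:
    """Normalize a conditioning collection to a (k, g) row matrix (k may be 0)."""
    if conditioning is None:
        return np.empty((0, 0))
    if isinstance(conditioning, np.ndarray) and conditioning.ndim == 2:
        return conditioning.astype(np.float64, copy=False)
    rows = [_vec(z) for z in conditioning]
    if not rows:
        return np.empty((0, 0))
    return np.vstack(rows)


def _design(Z: np.ndarray, g: int) -> np.ndarray:
    """Regression design: intercept column plus conditioning spectra."""
    if Z.size == 0:
        return np.ones((g, 1))
    return np.column_stack([np.ones(Z.shape[1]), Z.T])


def _residual(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def _check_residual(resid: np.ndarray, orig: np.ndarray, name: str) -> None:
    if np.std(resid) <= _RESIDUAL_REL_TOL * max(np.std(orig), 0.0) or np.std(resid) == 0.0:
        raise UndefinedSimilarityError(
            f"residual of {name} has (numerically) zero variance"
        )


def partial_similarity(x, yi, conditioning=()) -> float:
    """Partial correlation: Pearson correlation of both regression residuals.

    X and Y_i are each regressed (least squares, with intercept) on the
    conditioning spectra; rank-deficient designs are handled by the
    minimum-norm solution, whose residuals are the unique projection
    residuals.  An empty conditioning set reduces to Pearson correlation.
    """
    a, b = _vec(x), _vec(yi)
    Z = _conditioning_matrix(conditioning)
    if Z.size == 0:
        return _pearson(a, b)
    if Z.shape[1] != a.size or a.size != b.size:
        raise ValueError("spectra and conditioning set must share one m/z grid")
    A = _design(Z, a.size)
    ra = _residual(a, A)
    rb = _residual(b, A)
    _check_residual(ra, a, "X")
    _check_residual(rb, b, "Y_i")
    return _pearson(ra, rb)


def part_similarity(x, yi, conditioning=()) -> float:
    """Part (semipartial) correlation: raw X vs residual of Y_i only."""
    a, b = _vec(x), _vec(yi)
    Z = _conditioning_matrix(conditioning)
    if Z.size == 0:
        return _pearson(a, b)
    if Z.shape[1] != a.size or a.size != b.size:
        raise ValueError("spectra and conditioning set must share one m/z grid")
    A = _design(Z, a.size)
    rb = _residual(b, A)
    _check_residual(rb, b, "Y_i")
    return _pearson(a, rb)


def _pearson_row(a: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``a`` with every row of ``M``; NaN if undefined."""
    a0 = a - a.mean()
    na = np.linalg.norm(a0)
    M0 = M - M.mean(axis=1, keepdims=True)
    nm = np.linalg.norm(M0, axis=1)
    out = np.full(M.shape[0], np.nan)
    if na == 0.0:
        return out
    ok = nm > 0.0
    out[ok] = (M0[ok] @ a0) / (nm[ok] * na)
    return out


def _descending_order(r: np.ndarray) -> np.ndarray:
    """Indices sorted by score descending; ties and NaNs break to lower index."""
    key = np.where(np.isnan(r), -np.inf, r)
    return np.argsort(-key, kind="stable")


def two_step_conditioning_set(
    x, reference: PeakList, i: int, q: int
) -> tuple[int, ...]:
    """Y^(i,q): the q reference peaks most Pearson-correlated with X.

    Ranking is computed over Y^(i) (all reference peaks except i) in
    descending order of Pearson correlation with X; ties break to the lower
    reference index and undefined correlations rank last.  Order of the
    returned indices follows the ranking.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    a = _vec(x)
    r = _pearson_row(a, reference.spectra_matrix())
    order = [int(j) for j in _descending_order(r) if j != i]
    return tuple(order[:q])


def two_step_similarity(
    x, reference: PeakList, i: int, spec: SimilarityMeasureSpec
) -> float:
    """Two-step partial/part score of X vs reference peak i at rank spec.q."""
    if not spec.conditioned:
        raise ValueError("two-step form applies to partial/part measures only")
    if spec.q is None:
        raise ValueError("spec.q must be set for the two-step form")
    idx = two_step_conditioning_set(x, reference, i, spec.q)
    Z = np.vstack([reference[j].spectrum.intensities for j in idx]) if idx else np.empty((0, 0))
    fn = partial_similarity if spec.kind == "partial" else part_similarity
    return fn(x, reference[i].spectrum, Z)


# ---------------------------------------------------------------------------
# Pairwise matrices


def _cosine_block(T: np.ndarray, R: np.ndarray) -> np.ndarray:
    nt = np.linalg.norm(T, axis=1)
    nr = np.linalg.norm(R, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (T @ R.T) / np.outer(nt, nr)
    vals[nt == 0.0, :] = np.nan
    vals[:, nr == 0.0] = np.nan
    return vals


def _pearson_block(T: np.ndarray, R: np.ndarray) -> np.ndarray:
    T0 = T - T.mean(axis=1, keepdims=True)
    R0 = R - R.mean(axis=1, keepdims=True)
    return _cosine_block(T0, R0)


def _corr_with_columns(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``a`` with each column of ``B``."""
    a0 = a - a.mean()
    na = np.linalg.norm(a0)
    B0 = B - B.mean(axis=0, keepdims=True)
    nb = np.linalg.norm(B0, axis=0)
    out = np.full(B.shape[1], np.nan)
    if na == 0.0:
        return out
    ok = nb > 0.0
    out[ok] = (a0 @ B0[:, ok]) / (na * nb[ok])
    return out


def _conditioned_row(
    x: np.ndarray,
    R: np.ndarray,
    prerank: np.ndarray,
    kind: str,
    q: int | None,
) -> np.ndarray:
    """One target's partial/part scores against every reference peak.

    The conditioning set for pair (x, i) is the top-``q`` of the Pearson
    pre-ranking over Y^(i); with ``q`` None it is all of Y^(i).  References
    outside the global top-q share one conditioning set, so their residual
    regressions are solved in a single batched least-squares call; members
    of the top-q get individual leave-one-out designs.
    """
    m, g = R.shape
    out = np.full(m, np.nan)
    order = _descending_order(prerank)
    qq = m - 1 if q is None else min(q, m - 1)
    if qq <= 0:
        # single reference peak: empty conditioning set, plain Pearson
        return prerank.copy()
    S = order[:qq]
    S_plus = order[: qq + 1]
    in_S = np.zeros(m, dtype=bool)
    in_S[S] = True

    sd_x = np.std(x)
    # --- references outside the shared top-q window ---
    rest = np.flatnonzero(~in_S)
    if rest.size:
        A = _design(R[S], g)
        coef, *_ = np.linalg.lstsq(A, np.column_stack([x, R[rest].T]), rcond=None)
        resid = np.column_stack([x, R[rest].T]) - A @ coef
        rx = resid[:, 0]
        rY = resid[:, 1:]
        sd_rx = np.std(rx)
        sd_rY = np.std(rY, axis=0)
        sd_Y = np.std(R[rest], axis=1)
        ok = sd_rY > _RESIDUAL_REL_TOL * sd_Y
        if kind == "partial":
            if sd_rx > _RESIDUAL_REL_TOL * sd_x:
                vals = _corr_with_columns(rx, rY)
                vals[~ok] = np.nan
                out[rest] = vals
        else:
            vals = _corr_with_columns(x, rY)
            vals[~ok] = np.nan
            out[rest] = vals
    # --- members of the top-q: leave-one-out conditioning sets ---
    fn = partial_similarity if kind == "partial" else part_similarity
    for i in S:
        cond = R[[j for j in S_plus if j != i]]
        try:
            out[i] = fn(x, R[i], cond)
        except UndefinedSimilarityError:
            out[i] = np.nan
    return out


def similarity_matrix(
    target: PeakList, reference: PeakList, spec: SimilarityMeasureSpec
) -> SimilarityMatrix:
    """All pairwise scores; undefined entries become NaN, never errors.

    For two-step measures the conditioning set is recomputed per (target,
    reference) pair as in the single-pair operations.
    """
    if not np.array_equal(target.mz_grid, reference.mz_grid):
        raise ValueError("peak lists are on different m/z grids; harmonize first")
    T = target.spectra_matrix()
    R = reference.spectra_matrix()
    if spec.kind == "cosine":
        vals = _cosine_block(T, R)
    elif spec.kind == "pearson":
        vals = _pearson_block(T, R)
    elif spec.kind == "spearman":
        vals = _pearson_block(
            rankdata(T, axis=1).astype(np.float64),
            rankdata(R, axis=1).astype(np.float64),
        )
    else:
        prerank = _pearson_block(T, R)
        vals = np.vstack(
            [
                _conditioned_row(T[j], R, prerank[j], spec.kind, spec.q)
                for j in range(T.shape[0])
            ]
        )
    return SimilarityMatrix(values=vals, measure=spec)
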