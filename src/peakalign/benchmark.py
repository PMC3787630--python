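"""Parameter-sweep harness: every method × measure × parameter combination.

Produces one row per (run pair, method, measure, distance, parameter
combination) with confusion counts, TPR/FPR/PPV/F1 and AUC, plus a
mean/standard-error summary across run pairs — the reporting convention of
peak-alignment benchmark tables.  Similarity and distance matrices are
cached per pair so a grid over k/rho/w reuses them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .align import (
    METHODS,
    align_dw_pas,
    align_pad,
    align_pam,
    align_pas,
    align_sw_pad,
)
from .distance import DISTANCE_KINDS, DistanceMeasureSpec, distance_matrix
from .evaluate import alignment_roc, evaluate_alignment
from .model import PeakList, TruePairSet
from .similarity import MEASURE_KINDS, SimilarityMeasureSpec, similarity_matrix

__all__ = ["SweepGrid", "iter_combinations", "run_sweep", "summarize_sweep"]

ROW_COLUMNS = [
    "pair", "method", "measure", "distance", "k", "rho", "w", "q",
    "status", "TP", "FP", "FN", "TN", "TPR", "FPR", "PPV", "F1", "AUC",
    "m", "n", "s", "u",
]


@dataclass(frozen=True)
class SweepGrid:
    """Parameter grids for the benchmark sweep.

    Defaults: window ranks k in {3,5,10,15,20}; 13 equally spaced
    similarity cut-offs rho in [0.1, 0.99]; 13 equally spaced mixture
    weights w in [0.01, 0.99]; two-step ranks q in
    {3,5,7,10,15,20,30,50,70,100}.
    """

    methods: tuple[str, ...] = METHODS
    measures: tuple[str, ...] = MEASURE_KINDS
    distances: tuple[str, ...] = DISTANCE_KINDS
    k_values: tuple[int, ...] = (3, 5, 10, 15, 20)
    rho_values: tuple[float, ...] = tuple(np.round(np.linspace(0.1, 0.99, 13), 6))
    w_values: tuple[float, ...] = tuple(np.round(np.linspace(0.01, 0.99, 13), 6))
    q_values: tuple[int, ...] = (3, 5, 7, 10, 15, 20, 30, 50, 70, 100)

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        for m in self.measures:
            if m not in MEASURE_KINDS:
                raise ValueError(f"unknown measure {m!r}")
        for d in self.distances:
            if d not in DISTANCE_KINDS:
                raise ValueError(f"unknown distance {d!r}")


def _measure_specs(grid: SweepGrid) -> Iterator[SimilarityMeasureSpec]:
    for kind in grid.measures:
        if kind in ("partial", "part"):
            for q in grid.q_values:
                yield SimilarityMeasureSpec(kind, q=q)
        else:
            yield SimilarityMeasureSpec(kind)


def iter_combinations(grid: SweepGrid) -> Iterator[dict]:
    """Deterministic enumeration of every runnable combination."""
    for method in grid.methods:
        if method == "pad":
            for dist in grid.distances:
                yield {"method": "pad", "distance": dist}
        elif method == "pas":
            for spec in _measure_specs(grid):
                yield {"method": "pas", "sspec": spec}
        elif method == "dw_pas":
            for spec, dist, k in itertools.product(
                _measure_specs(grid), grid.distances, grid.k_values
            ):
                yield {"method": "dw_pas", "sspec": spec, "distance": dist, "k": k}
        elif method == "sw_pad":
            for spec, dist, rho in itertools.product(
                _measure_specs(grid), grid.distances, grid.rho_values
            ):
                yield {
                    "method": "sw_pad", "sspec": spec, "distance": dist, "rho": rho,
                }
        else:  # pam
            for spec, dist, w in itertools.product(
                _measure_specs(grid), grid.distances, grid.w_values
            ):
                yield {"method": "pam", "sspec": spec, "distance": dist, "w": w}


class _PairCache:
    """Per-pair cache of similarity and distance matrices."""

    def __init__(self, R: PeakList, T: PeakList):
        self.R, self.T = R, T
        self._sim: dict[tuple, object] = {}
        self._dist: dict[str, np.ndarray] = {}

    def sim(self, spec: SimilarityMeasureSpec):
        key = (spec.kind, spec.q)
        if key not in self._sim:
            self._sim[key] = similarity_matrix(self.T, self.R, spec)
        return self._sim[key]

    def dist(self, kind: str) -> np.ndarray:
        if kind not in self._dist:
            self._dist[kind] = distance_matrix(
                self.T, self.R, DistanceMeasureSpec(kind)
            )
        return self._dist[kind]


def _run_combo(cache: _PairCache, combo: dict):
    method = combo["method"]
    if method == "pad":
        dspec = DistanceMeasureSpec(combo["distance"])
        return align_pad(cache.T, cache.R, dspec, dist=cache.dist(dspec.kind))
    spec: SimilarityMeasureSpec = combo["sspec"]
    if spec.q is not None and spec.q >= len(cache.R):
        return None  # infeasible: rank exceeds reference size
    sim = cache.sim(spec)
    if method == "pas":
        return align_pas(cache.T, cache.R, spec, sim=sim)
    dspec = DistanceMeasureSpec(combo["distance"])
    dist = cache.dist(dspec.kind)
    if method == "dw_pas":
        return align_dw_pas(
            cache.T, cache.R, dspec, combo["k"], spec, sim=sim, dist=dist
        )
    if method == "sw_pad":
        return align_sw_pad(
            cache.T, cache.R, spec, combo["rho"], dspec, sim=sim, dist=dist
        )
    return align_pam(cache.T, cache.R, combo["w"], dspec, spec, sim=sim, dist=dist)


def _combo_row(combo: dict) -> dict:
    spec = combo.get("sspec")
    return {
        "method": combo["method"],
        "measure": spec.kind if spec else "",
        "distance": combo.get("distance", ""),
        "k": combo.get("k", np.nan),
        "rho": combo.get("rho", np.nan),
        "w": combo.get("w", np.nan),
        "q": (spec.q if spec and spec.q is not None else np.nan),
    }


def run_sweep(
    pairs: Iterable[tuple[PeakList, PeakList, TruePairSet]],
    grid: SweepGrid = SweepGrid(),
) -> pd.DataFrame:
    """Run every grid combination on every (R, T, truth) pair.

    Infeasible combinations (two-step rank q >= m) are flagged
    ``status='skipped'`` rather than failing the sweep.  AUC is NaN when a
    pair's matches are all-true or all-false at every cut-off.
    """
    rows = []
    for pair_id, (R, T, truth) in enumerate(pairs):
        cache = _PairCache(R, T)
        m, n = len(R), len(T)
        for combo in iter_combinations(grid):
            row = {"pair": pair_id, **_combo_row(combo)}
            result = _run_combo(cache, combo)
            if result is None:
                row["status"] = "skipped"
            else:
                row["status"] = "ok"
                report = evaluate_alignment(result, truth, m, n)
                row.update(report.to_dict())
                try:
                    row["AUC"] = alignment_roc(result, truth, m, n).auc
                except ValueError:
                    row["AUC"] = np.nan
            rows.append(row)
    df = pd.DataFrame(rows)
    for col in ROW_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[ROW_COLUMNS]


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of each metric across run pairs.

    SE is the standard deviation across pairs divided by sqrt(#pairs)
    (ddof=1; zero for a single pair).
    """
    keys = ["method", "measure", "distance", "k", "rho", "w", "q"]
    ok = df[df["status"] == "ok"].copy()
    metrics = ["TPR", "FPR", "PPV", "F1", "AUC"]

    def _agg(group: pd.DataFrame) -> pd.Series:
        out = {}
        npairs = len(group)
        for metric in metrics:
            vals = group[metric].to_numpy(dtype=float)
            out[f"{metric}_mean"] = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
            if npairs > 1 and np.isfinite(vals).sum() > 1:
                out[f"{metric}_se"] = np.nanstd(vals, ddof=1) / np.sqrt(
                    np.isfinite(vals).sum()
                )
            else:
                out[f"{metric}_se"] = 0.0 if np.isfinite(vals).any() else np.nan
        out["n_pairs"] = npairs
        return pd.Series(out)

    grouped = ok.groupby(keys, dropna=False, sort=True).apply(
        _agg, include_groups=False
    )
    return grouped.reset_index()
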