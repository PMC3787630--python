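"""Core data model for GC×GC-MS peak lists.

A detected compound peak carries two retention times (first- and
second-dimension column, both in seconds), an integrated area, and a
fragment-ion mass spectrum on an integer (nominal-mass) m/z grid.  A run's
peak list is an ordered collection of such peaks; ground-truth peak
correspondences between a reference and a target run are held in a
:class:`TruePairSet`.

Spectra are only comparable once all lists in a comparison share one m/z
grid; :func:`harmonize_mz_grid` re-expresses every spectrum on the union
grid, zero-filling absent channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "MassSpectrum",
    "Peak",
    "PeakList",
    "TruePairSet",
    "merge_peaks_by_area",
    "harmonize_mz_grid",
]


@dataclass(frozen=True, eq=False)
class MassSpectrum:
    """A fragment-ion spectrum: nonnegative intensities on an integer m/z grid.

    Parameters
    ----------
    mz_grid:
        Strictly increasing integer m/z values (nominal mass).
    intensities:
        Nonnegative intensities, same length as ``mz_grid``, arbitrary units.
        At least one channel must be nonzero.
    """

    mz_grid: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz_grid)
        if mz.dtype.kind == "f" and not np.all(mz == np.round(mz)):
            raise ValueError("m/z grid must contain integer values")
        mz = mz.astype(np.int64)
        inten = np.asarray(self.intensities, dtype=np.float64)
        if mz.ndim != 1 or inten.ndim != 1:
            raise ValueError("mz_grid and intensities must be 1-D")
        if mz.size == 0 or mz.size != inten.size:
            raise ValueError(
                f"grid/intensity length mismatch: {mz.size} vs {inten.size}"
            )
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z grid must be strictly increasing")
        if np.any(inten < 0) or not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite and nonnegative")
        if not np.any(inten > 0):
            raise ValueError("spectrum has no signal (all intensities zero)")
        mz.setflags(write=False)
        inten.setflags(write=False)
        object.__setattr__(self, "mz_grid", mz)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return int(self.mz_grid.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MassSpectrum):
            return NotImplemented
        return np.array_equal(self.mz_grid, other.mz_grid) and np.array_equal(
            self.intensities, other.intensities
        )

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())

    def reindex(self, new_grid: np.ndarray) -> "MassSpectrum":
        """Re-express on ``new_grid`` (a superset), zero-filling new channels."""
        new_grid = np.asarray(new_grid, dtype=np.int64)
        pos = np.searchsorted(new_grid, self.mz_grid)
        if np.any(pos >= new_grid.size) or np.any(new_grid[pos] != self.mz_grid):
            raise ValueError("new grid must be a superset of the current grid")
        out = np.zeros(new_grid.size, dtype=np.float64)
        out[pos] = self.intensities
        return MassSpectrum(new_grid, out)


@dataclass(frozen=True)
class Peak:
    """One detected compound peak in one run.

    ``rt1`` / ``rt2`` are first-/second-dimension retention times in seconds;
    ``area`` is the integrated peak area; ``label`` is an optional compound
    name (used for merging split peaks and for deriving ground truth in
    simulations).
    """

    rt1: float
    rt2: float
    area: float
    spectrum: MassSpectrum
    label: str | None = None

    def __post_init__(self) -> None:
        for name in ("rt1", "rt2", "area"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")
            object.__setattr__(self, name, v)
        if self.label is not None and not isinstance(self.label, str):
            raise TypeError("label must be a string or None")

    @property
    def rt(self) -> tuple[float, float]:
        return (self.rt1, self.rt2)


class PeakList(Sequence[Peak]):
    """Ordered peak list of one chromatographic run."""

    def __init__(
        self, peaks: Iterable[Peak], run_id: str = "", role: str = ""
    ) -> None:
        self.peaks: tuple[Peak, ...] = tuple(peaks)
        if not all(isinstance(p, Peak) for p in self.peaks):
            raise TypeError("PeakList members must be Peak instances")
        if role not in ("", "reference", "target"):
            raise ValueError(f"role must be 'reference' or 'target', got {role!r}")
        self.run_id = str(run_id)
        self.role = role

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i):  # type: ignore[override]
        if isinstance(i, slice):
            return PeakList(self.peaks[i], run_id=self.run_id, role=self.role)
        return self.peaks[i]

    def __repr__(self) -> str:
        return (
            f"PeakList(n={len(self)}, run_id={self.run_id!r}, role={self.role!r})"
        )

    @property
    def mz_grid(self) -> np.ndarray:
        """The shared m/z grid; raises if spectra are not harmonized."""
        if not self.peaks:
            raise ValueError("empty peak list has no grid")
        grid = self.peaks[0].spectrum.mz_grid
        for p in self.peaks[1:]:
            if not np.array_equal(p.spectrum.mz_grid, grid):
                raise ValueError(
                    "peak list spectra are on different m/z grids; "
                    "run harmonize_mz_grid first"
                )
        return grid

    def rts(self) -> np.ndarray:
        """(n, 2) array of (rt1, rt2)."""
        return np.array([(p.rt1, p.rt2) for p in self.peaks], dtype=np.float64)

    def spectra_matrix(self) -> np.ndarray:
        """(n, g) intensity matrix on the shared grid."""
        self.mz_grid  # validates harmonization
        return np.vstack([p.spectrum.intensities for p in self.peaks])

    def labels(self) -> list[str | None]:
        return [p.label for p in self.peaks]

    def with_peaks(self, peaks: Iterable[Peak]) -> "PeakList":
        return PeakList(peaks, run_id=self.run_id, role=self.role)


@dataclass(frozen=True)
class TruePairSet:
    """Ground-truth (reference index, target index) peak correspondences.

    Indices are 0-based positions in the (merged) reference and target peak
    lists; each index appears at most once on its side (one-to-one).
    """

    pairs: frozenset

    def __init__(self, pairs: Iterable[tuple[int, int]]) -> None:
        fs = frozenset((int(r), int(t)) for r, t in pairs)
        refs = [r for r, _ in fs]
        tgts = [t for _, t in fs]
        if len(set(refs)) != len(refs) or len(set(tgts)) != len(tgts):
            raise ValueError("true pairs must be one-to-one (no repeated index)")
        if any(r < 0 or t < 0 for r, t in fs):
            raise ValueError("true-pair indices must be nonnegative")
        object.__setattr__(self, "pairs", fs)

    @property
    def s(self) -> int:
        """Number of true peak pairs."""
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs


def merge_peaks_by_area(pl: PeakList) -> PeakList:
    """Collapse peaks sharing a compound label, keeping the largest area.

    Deconvolution software frequently reports several peaks for one compound;
    for each distinct label only the peak with maximal area is retained (ties
    break toward the earliest occurrence).  Unlabeled peaks pass through
    unchanged.  Output order is the order of first occurrence.
    """
    best: dict[str, int] = {}
    order: list[tuple[str, object]] = []
    for idx, p in enumerate(pl):
        if p.label is None:
            order.append(("peak", idx))
        elif p.label not in best:
            best[p.label] = idx
            order.append(("label", p.label))
        elif p.area > pl[best[p.label]].area:
            best[p.label] = idx
    merged = [
        pl[key] if kind == "peak" else pl[best[key]]  # type: ignore[index]
        for kind, key in order
    ]
    return pl.with_peaks(merged)


def harmonize_mz_grid(lists: Iterable[PeakList]) -> list[PeakList]:
    """Re-express all spectra in all lists on the union m/z grid.

    Channels absent from a spectrum's original grid are zero-filled, so each
    spectrum's total ion intensity is conserved and the grid never shrinks.
    """
    lists = list(lists)
    if not lists:
        raise ValueError("need at least one peak list")
    grids = [p.spectrum.mz_grid for pl in lists for p in pl]
    if not grids:
        return lists
    union = np.unique(np.concatenate(grids))
    out = []
    for pl in lists:
        out.append(
            pl.with_peaks(
                replace(p, spectrum=p.spectrum.reindex(union)) for p in pl
            )
        )
    return out
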