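"""Synthetic GC×GC-MS run-pair generator with known ground truth.

Two regimes are emulated.  The sparse regime ("data1_like") mimics a
mixture of ~75 compound standards: mostly distinct fragment spectra, high
alignment accuracy.  The dense regime ("data2_like") mimics a biological
extract with ~450 detected compounds whose spectra are dominated by a
common pool of fragment ions (as TMS-derivatized metabolite spectra are),
producing strong inter-compound spectral correlation — the regime where
conditioning-based similarity measures pay off.

Each compound has a base spectrum built from fragments drawn partly from a
shared pool (shared fragments carry a characteristic intensity reused
across compounds, modulated per compound) and partly from the remaining
channels, plus uniform retention times.  A run pair shares s compounds,
each re-observed with independent Gaussian retention-time jitter and
multiplicative log-normal spectral noise followed by a detection floor;
extra unshared compounds are appended to both lists as decoys.  All
randomness flows from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .model import MassSpectrum, Peak, PeakList, TruePairSet

__all__ = [
    "SyntheticConfig",
    "Compound",
    "generate_compound_library",
    "generate_run_pair",
    "add_split_peaks",
    "truth_from_labels",
    "data1_like",
    "data2_like",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults correspond to the sparse regime.

    ``shared_fraction`` fixes s = round(shared_fraction · n_compounds) true
    pairs; ``extra_ref``/``extra_target`` decoy compounds appear in only one
    list.  ``shared_fragment_fraction`` of each compound's fragments come
    from a pool of ``shared_fragment_pool`` channels with characteristic
    intensities, which is what induces inter-compound spectral correlation.
    Retention times are in seconds; jitter SDs are per dimension.
    ``spectral_noise_cv`` is the per-channel coefficient of variation of the
    multiplicative log-normal noise on true fragment channels;
    ``baseline_noise`` is the mean of additive exponential chemical/detector
    noise applied to every channel (in base-peak-100 units), the component
    that scrambles the ranks of low-intensity channels; channels falling
    below ``detection_floor`` × (spectrum max) are then zeroed.
    """

    n_compounds: int = 75
    shared_fraction: float = 0.9
    extra_ref: int = 7
    extra_target: int = 7
    g: int = 120
    mz_start: int = 50
    n_fragments_per_compound: int = 15
    shared_fragment_pool: int = 30
    shared_fragment_fraction: float = 0.3
    rt1_range: tuple[float, float] = (300.0, 3300.0)
    rt2_range: tuple[float, float] = (0.5, 5.5)
    rt_jitter_sd: tuple[float, float] = (3.0, 0.05)
    spectral_noise_cv: float = 0.25
    baseline_noise: float = 0.0
    detection_floor: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.g < 2:
            raise ValueError("need at least one compound and two m/z channels")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.extra_ref < 0 or self.extra_target < 0:
            raise ValueError("extra peak counts must be nonnegative")
        if self.n_fragments_per_compound < 1:
            raise ValueError("need at least one fragment per compound")
        if not 0.0 <= self.shared_fragment_fraction <= 1.0:
            raise ValueError("shared_fragment_fraction must lie in [0, 1]")
        if min(self.rt_jitter_sd) < 0 or self.spectral_noise_cv < 0:
            raise ValueError("jitter SDs and noise CV must be nonnegative")
        if self.baseline_noise < 0:
            raise ValueError("baseline_noise must be nonnegative")
        if not 0.0 <= self.detection_floor < 1.0:
            raise ValueError("detection_floor is a fraction of the base peak")

    @property
    def s(self) -> int:
        """Number of true (shared) peak pairs implied by the config."""
        return round(self.shared_fraction * self.n_compounds)


class Compound(NamedTuple):
    label: str
    intensities: np.ndarray  # base spectrum on the full grid
    rt1: float
    rt2: float


def _mz_grid(cfg: SyntheticConfig) -> np.ndarray:
    return np.arange(cfg.mz_start, cfg.mz_start + cfg.g, dtype=np.int64)


def generate_compound_library(
    cfg: SyntheticConfig, n: int | None = None, rng: np.random.Generator | None = None
) -> list[Compound]:
    """Draw ``n`` compounds (default cfg.n_compounds) from the config's regime."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_compounds if n is None else int(n)
    pool_size = min(cfg.shared_fragment_pool, cfg.g)
    pool = rng.choice(cfg.g, size=pool_size, replace=False)
    # characteristic pool intensities, reused (modulated) across compounds
    pool_base = rng.lognormal(mean=math.log(60.0), sigma=0.6, size=pool_size)
    non_pool = np.setdiff1d(np.arange(cfg.g), pool)
    compounds = []
    for c in range(n):
        n_sh = min(round(cfg.shared_fragment_fraction * cfg.n_fragments_per_compound),
                   pool_size)
        n_un = cfg.n_fragments_per_compound - n_sh
        intens = np.zeros(cfg.g)
        if n_sh > 0:
            pick = rng.choice(pool_size, size=n_sh, replace=False)
            intens[pool[pick]] = pool_base[pick] * rng.lognormal(0.0, 0.4, n_sh)
        if n_un > 0 and non_pool.size > 0:
            un = rng.choice(non_pool, size=min(n_un, non_pool.size), replace=False)
            intens[un] = rng.lognormal(math.log(25.0), 1.0, un.size)
        if not np.any(intens > 0):  # degenerate config fallback: one fragment
            intens[int(rng.integers(cfg.g))] = 100.0
        intens *= 100.0 / intens.max()  # base-peak normalization
        compounds.append(
            Compound(
                label=f"M{c:04d}",
                intensities=intens,
                rt1=float(rng.uniform(*cfg.rt1_range)),
                rt2=float(rng.uniform(*cfg.rt2_range)),
            )
        )
    return compounds


def _noisy_spectrum(
    base: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    v = base.astype(np.float64).copy()
    if cfg.spectral_noise_cv > 0:
        sigma = math.sqrt(math.log1p(cfg.spectral_noise_cv**2))
        # mean-one multiplicative noise per channel
        v *= rng.lognormal(-0.5 * sigma**2, sigma, v.size)
    if cfg.baseline_noise > 0:
        v += rng.exponential(cfg.baseline_noise, v.size)
    if cfg.detection_floor > 0:
        v[v < cfg.detection_floor * v.max()] = 0.0
    return v


def _observe(
    comp: Compound, cfg: SyntheticConfig, rng: np.random.Generator, grid: np.ndarray
) -> Peak:
    rt1 = max(0.0, comp.rt1 + rng.normal(0.0, cfg.rt_jitter_sd[0]))
    rt2 = max(0.0, comp.rt2 + rng.normal(0.0, cfg.rt_jitter_sd[1]))
    intens = _noisy_spectrum(comp.intensities, cfg, rng)
    area = float(intens.sum() * rng.lognormal(0.0, 0.3))
    return Peak(rt1=rt1, rt2=rt2, area=area, spectrum=MassSpectrum(grid, intens),
                label=comp.label)


def generate_run_pair(
    cfg: SyntheticConfig,
) -> tuple[PeakList, PeakList, TruePairSet]:
    """One reference/target run pair with ground-truth correspondences.

    Both runs share the same retention-time ranges (homogeneous data: runs
    acquired under identical instrument conditions).  Lists are sorted by
    (rt1, rt2) as an instrument export would be; the returned TruePairSet
    indexes the sorted lists.
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.s
    lib = generate_compound_library(
        cfg, n=s + cfg.extra_ref + cfg.extra_target, rng=rng
    )
    shared = lib[:s]
    ref_only = lib[s : s + cfg.extra_ref]
    tgt_only = lib[s + cfg.extra_ref :]
    grid = _mz_grid(cfg)
    ref_peaks = [_observe(c, cfg, rng, grid) for c in shared + ref_only]
    tgt_peaks = [_observe(c, cfg, rng, grid) for c in shared + tgt_only]
    ref_peaks.sort(key=lambda p: (p.rt1, p.rt2))
    tgt_peaks.sort(key=lambda p: (p.rt1, p.rt2))
    R = PeakList(ref_peaks, run_id=f"sim-ref-{cfg.seed}", role="reference")
    T = PeakList(tgt_peaks, run_id=f"sim-tgt-{cfg.seed}", role="target")
    return R, T, truth_from_labels(R, T)


def truth_from_labels(R: PeakList, T: PeakList) -> TruePairSet:
    """Ground truth from shared compound labels (must be unique per list)."""
    ref_idx: dict[str, int] = {}
    for i, p in enumerate(R):
        if p.label is not None:
            if p.label in ref_idx:
                raise ValueError(
                    f"duplicate label {p.label!r} in reference list; merge first"
                )
            ref_idx[p.label] = i
    pairs = []
    seen: set[str] = set()
    for j, p in enumerate(T):
        if p.label is not None:
            if p.label in seen:
                raise ValueError(
                    f"duplicate label {p.label!r} in target list; merge first"
                )
            seen.add(p.label)
            if p.label in ref_idx:
                pairs.append((ref_idx[p.label], j))
    return TruePairSet(pairs)


def add_split_peaks(
    pl: PeakList, n_extra: int, rng: np.random.Generator
) -> PeakList:
    """Append deconvolution-style split peaks: same label, smaller area.

    Emulates software reporting several peaks per compound so that
    merge-by-area has something to do.  Split peaks sit close in retention
    time and always have strictly smaller area than their parent.
    """
    if len(pl) == 0 or n_extra <= 0:
        return pl
    peaks = list(pl.peaks)
    labeled = [p for p in pl if p.label is not None]
    if not labeled:
        raise ValueError("split peaks require labeled parents")
    for _ in range(n_extra):
        parent = labeled[int(rng.integers(len(labeled)))]
        peaks.append(
            Peak(
                rt1=max(0.0, parent.rt1 + float(rng.normal(0.0, 1.0))),
                rt2=max(0.0, parent.rt2 + float(rng.normal(0.0, 0.02))),
                area=parent.area * float(rng.uniform(0.05, 0.8)),
                spectrum=parent.spectrum,
                label=parent.label,
            )
        )
    return pl.with_peaks(peaks)


def data1_like(**overrides) -> SyntheticConfig:
    """Sparse mixture-of-standards regime (~75 peaks/run)."""
    base = dict(
        n_compounds=75,
        shared_fraction=0.9,
        extra_ref=7,
        extra_target=7,
        g=120,
        n_fragments_per_compound=15,
        shared_fragment_pool=30,
        shared_fragment_fraction=0.45,
        spectral_noise_cv=0.45,
        baseline_noise=2.5,
        rt_jitter_sd=(3.0, 0.05),
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def data2_like(**overrides) -> SyntheticConfig:
    """Dense biological regime (~450 peaks/run, strongly correlated spectra)."""
    base = dict(
        n_compounds=450,
        shared_fraction=0.9,
        extra_ref=20,
        extra_target=20,
        g=160,
        n_fragments_per_compound=20,
        shared_fragment_pool=30,
        shared_fragment_fraction=0.8,
        spectral_noise_cv=0.7,
        baseline_noise=2.5,
        rt_jitter_sd=(4.0, 0.08),
    )
    base.update(overrides)
    return SyntheticConfig(**base)


PRESETS = {"data1_like": data1_like, "data2_like": data2_like}


def preset(name: str, **overrides) -> SyntheticConfig:
    """Look up a named preset, optionally overriding fields."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; expected one of {sorted(PRESETS)}"
        ) from None
    return factory(**overrides)
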