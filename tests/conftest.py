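from __future__ import annotations

import numpy as np
import pytest

from peakalign import MassSpectrum, Peak, PeakList


def random_spectrum(rng: np.random.Generator, g: int, mz_start: int = 50):
    """A random nonnegative, non-constant spectrum on an integer grid."""
    intens = rng.lognormal(2.0, 1.0, g) * rng.binomial(1, 0.7, g)
    if not intens.any():
        intens[rng.integers(g)] = 10.0
    return MassSpectrum(np.arange(mz_start, mz_start + g), intens)


def random_peak_list(
    rng: np.random.Generator,
    n: int,
    g: int = 20,
    role: str = "",
    labels: bool = False,
) -> PeakList:
    peaks = [
        Peak(
            rt1=float(rng.uniform(0, 2000)),
            rt2=float(rng.uniform(0, 6)),
            area=float(rng.uniform(10, 1e4)),
            spectrum=random_spectrum(rng, g),
            label=f"C{i}" if labels else None,
        )
        for i in range(n)
    ]
    return PeakList(peaks, run_id="rand", role=role)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def spectrum(intensities, mz_start: int = 50) -> MassSpectrum:
    intensities = np.asarray(intensities, dtype=float)
    return MassSpectrum(np.arange(mz_start, mz_start + intensities.size), intensities)


def peak(rt1=0.0, rt2=0.0, area=1.0, intens=(1.0, 2.0), label=None) -> Peak:
    return Peak(rt1=rt1, rt2=rt2, area=area, spectrum=spectrum(intens), label=label)
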