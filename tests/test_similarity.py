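"""The five spectral similarity measures and their two-step variants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakalign import (
    PeakList,
    SimilarityMeasureSpec,
    UndefinedSimilarityError,
    cosine_similarity,
    part_similarity,
    partial_similarity,
    pearson_similarity,
    similarity_matrix,
    spearman_similarity,
    two_step_conditioning_set,
    two_step_similarity,
)
from conftest import peak, random_peak_list, random_spectrum
from oracles import (
    conditioning_set_oracle,
    pair_score,
    part_oracle,
    partial_oracle,
)


class TestBasicMeasures:
    def test_cosine_hand_values(self):
        assert cosine_similarity([1, 0], [0, 1]) == 0.0
        assert cosine_similarity([1, 2, 2], [2, 4, 4]) == pytest.approx(1.0)
        assert cosine_similarity([3, 4], [4, 3]) == pytest.approx(24 / 25)

    def test_pearson_hand_values(self):
        assert pearson_similarity([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_similarity([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)
        assert pearson_similarity([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_spearman_hand_values(self):
        # ranks (1,2,3) vs (3,1,2)
        assert spearman_similarity([1, 2, 3], [9, 1, 5]) == pytest.approx(-0.5)
        # strictly monotone transform of x has correlation 1 with x
        x = np.array([3.0, 1.0, 7.0, 2.0])
        assert spearman_similarity(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_similarity(x, -x) == pytest.approx(-1.0)

    def test_undefined_scores_raise(self):
        with pytest.raises(UndefinedSimilarityError):
            pearson_similarity([2, 2, 2], [1, 2, 3])
        with pytest.raises(UndefinedSimilarityError):
            spearman_similarity([1, 2, 3], [5, 5, 5])

    @given(scale=st.floats(0.01, 1e4))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        x = np.array([3.0, 0.0, 7.0, 2.0, 9.0])
        y = np.array([1.0, 4.0, 2.0, 8.0, 3.0])
        for fn in (cosine_similarity, pearson_similarity, spearman_similarity):
            assert fn(x, scale * y) == pytest.approx(fn(x, y), abs=1e-12)

    def test_symmetry_and_ranges(self, rng):
        for _ in range(20):
            x = random_spectrum(rng, 15).intensities
            y = random_spectrum(rng, 15).intensities
            c = cosine_similarity(x, y)
            assert 0.0 <= c <= 1.0  # nonnegative spectra
            assert c == pytest.approx(cosine_similarity(y, x))
            p = pearson_similarity(x, y)
            assert -1.0 <= p <= 1.0
            assert p == pytest.approx(pearson_similarity(y, x))
            assert -1.0 <= spearman_similarity(x, y) <= 1.0


class TestConditionedMeasures:
    def test_empty_conditioning_reduces_to_pearson(self, rng):
        x = random_spectrum(rng, 12).intensities
        y = random_spectrum(rng, 12).intensities
        expected = pearson_similarity(x, y)
        assert partial_similarity(x, y, ()) == expected
        assert part_similarity(x, y, ()) == expected

    def test_independence_identity(self, rng):
        # construct z sample-orthogonal to both x and y via Gram-Schmidt
        for _ in range(20):
            g = 24
            x = rng.lognormal(2, 1, g)
            y = rng.lognormal(2, 1, g)
            z = rng.normal(0, 1, g)
            basis, _ = np.linalg.qr(np.column_stack([np.ones(g), x, y]))
            z = z - basis @ (basis.T @ z)
            assert abs(np.cov(x, z)[0, 1]) < 1e-9
            assert abs(np.cov(y, z)[0, 1]) < 1e-9
            p0 = pearson_similarity(x, y)
            assert partial_similarity(x, y, [z]) == pytest.approx(p0, abs=1e-10)
            assert part_similarity(x, y, [z]) == pytest.approx(p0, abs=1e-10)

    def test_against_residual_regression_oracle(self):
        x = np.array([2.0, 4.0, 6.0, 9.0])
        yi = np.array([1.0, 2.0, 3.0, 5.0])
        z = np.array([[1.0, 1.0, 2.0, 2.0]])
        got_partial = partial_similarity(x, yi, z)
        got_part = part_similarity(x, yi, z)
        assert got_partial == pytest.approx(partial_oracle(x, yi, z), abs=1e-10)
        assert got_part == pytest.approx(part_oracle(x, yi, z), abs=1e-10)
        assert got_partial != pytest.approx(got_part, abs=1e-6)

    def test_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            g = 30
            x = rng.normal(0, 1, g)
            y = 0.5 * x + rng.normal(0, 1, g)
            Z = rng.normal(0, 1, (2, g))
            df = pd.DataFrame({"x": x, "y": y, "z0": Z[0], "z1": Z[1]})
            ref_partial = pingouin.partial_corr(
                df, x="x", y="y", covar=["z0", "z1"]
            )["r"].iloc[0]
            ref_part = pingouin.partial_corr(
                df, x="x", y="y", y_covar=["z0", "z1"]
            )["r"].iloc[0]
            assert partial_similarity(x, y, Z) == pytest.approx(ref_partial, abs=1e-8)
            assert part_similarity(x, y, Z) == pytest.approx(ref_part, abs=1e-8)

    def test_part_is_asymmetric(self):
        x = np.array([2.0, 4.0, 6.0, 9.0, 1.0])
        y = np.array([1.0, 2.0, 5.0, 5.0, 3.0])
        z = np.array([[1.0, 3.0, 2.0, 2.0, 7.0]])
        assert part_similarity(x, y, z) != pytest.approx(
            part_similarity(y, x, z), abs=1e-6
        )

    def test_duplicate_conditioning_spectrum_does_not_crash(self, rng):
        # yi duplicated inside the conditioning set: residual is ~0
        x = rng.lognormal(2, 1, 20)
        yi = rng.lognormal(2, 1, 20)
        with pytest.raises(UndefinedSimilarityError):
            partial_similarity(x, yi, [yi.copy(), rng.lognormal(2, 1, 20)])


class TestTwoStep:
    def test_window_covers_everything(self, rng):
        ref = random_peak_list(rng, 6, g=30)
        x = random_spectrum(rng, 30)
        got = two_step_conditioning_set(x, ref, 2, q=10)
        assert sorted(got) == [0, 1, 3, 4, 5]

    def test_matches_full_ranking_oracle(self, rng):
        for trial in range(25):
            m = int(rng.integers(4, 10))
            ref = random_peak_list(rng, m, g=25)
            x = random_spectrum(rng, 25)
            i = int(rng.integers(m))
            q = int(rng.integers(2, 6))
            assert two_step_conditioning_set(x, ref, i, q) == \
                conditioning_set_oracle(x, ref, i, q)

    def test_self_excluded_even_when_top_ranked(self, rng):
        ref = random_peak_list(rng, 8, g=30)
        x = ref[3].spectrum  # identical to peak 3 -> pearson 1, top rank
        got = two_step_conditioning_set(x, ref, 3, q=3)
        assert 3 not in got
        assert len(got) == 3

    def test_reduces_to_full_conditioning(self, rng):
        m, g = 6, 40  # g > m so the full design is identifiable
        ref = random_peak_list(rng, m, g=g)
        x = random_spectrum(rng, g)
        for kind in ("partial", "part"):
            full_z = [ref[j].spectrum.intensities for j in range(m) if j != 2]
            fn = partial_similarity if kind == "partial" else part_similarity
            expected = fn(x, ref[2].spectrum, full_z)
            spec = SimilarityMeasureSpec(kind, q=m - 1)
            # conditioning-set ordering differs from index order but spans
            # the same space, so residuals and hence scores agree
            assert two_step_similarity(x, ref, 2, spec) == pytest.approx(
                expected, abs=1e-9
            )

    def test_two_step_matches_residual_oracle(self, rng):
        for trial in range(20):
            m = int(rng.integers(4, 9))
            ref = random_peak_list(rng, m, g=30)
            x = random_spectrum(rng, 30)
            i = int(rng.integers(m))
            q = int(rng.integers(2, 5))
            Z = np.vstack(
                [ref[j].spectrum.intensities
                 for j in conditioning_set_oracle(x, ref, i, q)]
            )
            for kind, oracle in (("partial", partial_oracle), ("part", part_oracle)):
                spec = SimilarityMeasureSpec(kind, q=q)
                got = two_step_similarity(x.intensities, ref, i, spec)
                assert got == pytest.approx(
                    oracle(x.intensities, ref[i].spectrum.intensities, Z),
                    abs=1e-10,
                )

    def test_duplicate_reference_peak_gives_nan_not_crash(self, rng):
        peaks = list(random_peak_list(rng, 5, g=25).peaks)
        peaks.append(peaks[2])  # exact duplicate of peak 2
        ref = PeakList(peaks)
        x = random_spectrum(rng, 25)
        spec = SimilarityMeasureSpec("partial", q=5)
        S = similarity_matrix(PeakList([peaks[2]]), ref, spec).values
        assert S.shape == (1, 6)  # computed without raising


class TestSimilarityMatrix:
    def test_single_pair_matches_scalar_call(self, rng):
        t = random_peak_list(rng, 1, g=15)
        r = random_peak_list(rng, 1, g=15)
        S = similarity_matrix(t, r, SimilarityMeasureSpec("cosine")).values
        assert S.shape == (1, 1)
        assert S[0, 0] == pytest.approx(
            cosine_similarity(t[0].spectrum, r[0].spectrum)
        )

    def test_self_cosine_diagonal_is_one(self, rng):
        pl = random_peak_list(rng, 6, g=20)
        S = similarity_matrix(pl, pl, SimilarityMeasureSpec("cosine")).values
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-12)

    @pytest.mark.parametrize(
        "spec",
        [
            SimilarityMeasureSpec("cosine"),
            SimilarityMeasureSpec("pearson"),
            SimilarityMeasureSpec("spearman"),
            SimilarityMeasureSpec("partial", q=3),
            SimilarityMeasureSpec("part", q=3),
            SimilarityMeasureSpec("partial"),
            SimilarityMeasureSpec("part"),
        ],
        ids=lambda s: s.describe(),
    )
    def test_every_entry_matches_pairwise_brute_force(self, rng, spec):
        T = random_peak_list(rng, 5, g=30)
        R = random_peak_list(rng, 7, g=30)
        S = similarity_matrix(T, R, spec).values
        for j in range(5):
            for i in range(7):
                expected = pair_score(T[j], R, i, _full_as_two_step(spec, R))
                if expected is None:
                    assert np.isnan(S[j, i])
                else:
                    assert S[j, i] == pytest.approx(expected, abs=1e-10)


def _full_as_two_step(spec, R):
    """Full conditioning equals the two-step form at q = m - 1."""
    if spec.kind in ("partial", "part") and spec.q is None:
        return SimilarityMeasureSpec(spec.kind, q=len(R) - 1)
    return spec
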