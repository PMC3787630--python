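"""Domain types, the peak-table dialect, merging and grid harmonization."""

from __future__ import annotations

import numpy as np
import pytest

from peakalign import (
    MassSpectrum,
    Peak,
    PeakList,
    PeakTableFormatError,
    TruePairSet,
    add_split_peaks,
    data1_like,
    generate_run_pair,
    harmonize_mz_grid,
    merge_peaks_by_area,
    read_peak_table,
    read_true_pairs,
    write_peak_table,
    write_true_pairs,
)
from conftest import peak, random_peak_list, spectrum


class TestMassSpectrum:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MassSpectrum([70, 75], [1.0, -0.5])  # negative intensity
        with pytest.raises(ValueError):
            MassSpectrum([70, 75], [0.0, 0.0])  # no signal
        with pytest.raises(ValueError):
            MassSpectrum([75, 70], [1.0, 2.0])  # unordered grid
        with pytest.raises(ValueError):
            MassSpectrum([70, 75, 80], [1.0, 2.0])  # length mismatch

    def test_reindex_zero_fills_and_conserves(self):
        s = MassSpectrum([70, 75], [12.0, 100.0])
        out = s.reindex(np.array([70, 75, 80]))
        assert np.array_equal(out.intensities, [12.0, 100.0, 0.0])
        assert out.total_intensity == s.total_intensity


class TestPeakTableDialect:
    def test_row_maps_to_fields(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "rt1,rt2,area,label,spectrum\n120.5,2.31,1000,glycine,70:12 75:100\n"
        )
        pl = read_peak_table(p)
        assert len(pl) == 1
        pk = pl[0]
        assert (pk.rt1, pk.rt2, pk.area, pk.label) == (120.5, 2.31, 1000.0, "glycine")
        assert np.array_equal(pk.spectrum.mz_grid, [70, 75])
        assert np.array_equal(pk.spectrum.intensities, [12.0, 100.0])

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "rt1,rt2,area,label,spectrum\n"
            "1,1,10,a,70:1\n2,2,20,b,70:2\n3,3,30,c,70:3\n"
        )
        assert [pk.label for pk in read_peak_table(p)] == ["a", "b", "c"]

    @pytest.mark.parametrize(
        "row,fragment",
        [
            ("120,2,100,x,", "empty spectrum"),
            ("120,2,100,x,70.5:10", "non-integer m/z"),
            ("120,2,100,x,70:-3", "negative intensity"),
            ("abc,2,100,x,70:10", "rt1"),
        ],
    )
    def test_malformed_rows_rejected_not_dropped(self, tmp_path, row, fragment):
        p = tmp_path / "t.csv"
        p.write_text(f"rt1,rt2,area,label,spectrum\n{row}\n")
        with pytest.raises(PeakTableFormatError, match="row 1"):
            read_peak_table(p)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("rt1,rt2,label,spectrum\n1,2,x,70:1\n")
        with pytest.raises(PeakTableFormatError, match="'area'"):
            read_peak_table(p)

    def test_round_trip_is_lossless(self, tmp_path, rng):
        pl = random_peak_list(rng, 10, labels=True)
        # include one unlabeled peak: its label cell must stay empty
        pl = pl.with_peaks(list(pl.peaks) + [peak(rt1=5.0, intens=(1, 2, 3))])
        out = tmp_path / "rt.csv"
        write_peak_table(pl, out)
        back = read_peak_table(out)
        assert len(back) == len(pl)
        assert "None" not in out.read_text()
        for a, b in zip(pl, back):
            assert a.label == b.label
            assert a.rt1 == pytest.approx(b.rt1, rel=1e-6)
            assert a.area == pytest.approx(b.area, rel=1e-6)
            assert np.array_equal(a.spectrum.mz_grid, b.spectrum.mz_grid)
            np.testing.assert_allclose(
                a.spectrum.intensities, b.spectrum.intensities, rtol=1e-6
            )


class TestMergeByArea:
    def test_largest_area_survives(self):
        pl = PeakList(
            [
                peak(rt1=1, area=100, label="alanine"),
                peak(rt1=2, area=200, label="alanine"),
            ]
        )
        merged = merge_peaks_by_area(pl)
        assert len(merged) == 1
        assert merged[0].area == 200

    def test_distinct_labels_identity(self, rng):
        pl = random_peak_list(rng, 8, labels=True)
        assert merge_peaks_by_area(pl).peaks == pl.peaks

    def test_unlabeled_pass_through_and_order(self):
        pl = PeakList(
            [
                peak(rt1=1, area=10, label="a"),
                peak(rt1=2, area=5),
                peak(rt1=3, area=99, label="a"),
                peak(rt1=4, area=7, label="b"),
            ]
        )
        merged = merge_peaks_by_area(pl)
        assert [p.label for p in merged] == ["a", None, "b"]
        assert merged[0].area == 99  # winner placed at first occurrence

    def test_tie_breaks_to_earliest(self):
        pl = PeakList(
            [peak(rt1=1, area=50, label="x"), peak(rt1=2, area=50, label="x")]
        )
        assert merge_peaks_by_area(pl)[0].rt1 == 1

    def test_split_peak_fixture_matches_groupby_oracle(self, rng):
        # 78 compounds inflated to 180 peaks, as deconvolution software does
        cfg = data1_like(seed=5, n_compounds=78, shared_fraction=1.0,
                         extra_ref=0, extra_target=0)
        R, _, _ = generate_run_pair(cfg)
        inflated = add_split_peaks(R, 180 - len(R), rng)
        assert len(inflated) == 180
        merged = merge_peaks_by_area(inflated)
        assert len(merged) == 78
        # brute-force group-by-label max-area oracle
        expect = {}
        for p in inflated:
            if p.label not in expect or p.area > expect[p.label].area:
                expect[p.label] = p
        assert {p.label: p.area for p in merged} == {
            k: v.area for k, v in expect.items()
        }

    def test_idempotent(self, rng):
        pl = add_split_peaks(random_peak_list(rng, 10, labels=True), 15, rng)
        once = merge_peaks_by_area(pl)
        assert merge_peaks_by_area(once).peaks == once.peaks

    def test_empty_list(self):
        assert len(merge_peaks_by_area(PeakList([]))) == 0


class TestHarmonize:
    def test_union_and_zero_fill(self):
        a = PeakList([Peak(1, 1, 1, MassSpectrum([70, 75], [12, 100]))])
        b = PeakList([Peak(2, 2, 2, MassSpectrum([75, 80], [5, 7]))])
        ha, hb = harmonize_mz_grid([a, b])
        assert np.array_equal(ha[0].spectrum.mz_grid, [70, 75, 80])
        assert np.array_equal(ha[0].spectrum.intensities, [12, 100, 0])
        assert np.array_equal(hb[0].spectrum.intensities, [0, 5, 7])

    def test_identical_grids_unchanged_and_conserving(self, rng):
        pl = random_peak_list(rng, 6)
        (out,) = harmonize_mz_grid([pl])
        for a, b in zip(pl, out):
            assert a.spectrum == b.spectrum
            assert a.spectrum.total_intensity == b.spectrum.total_intensity

    def test_grid_never_shrinks_and_conserves(self, rng):
        a = random_peak_list(rng, 4, g=15)
        b = random_peak_list(rng, 4, g=25)
        ha, hb = harmonize_mz_grid([a, b])
        g_union = ha.mz_grid
        assert g_union.size >= 25
        for before, after in zip(list(a) + list(b), list(ha) + list(hb)):
            assert after.spectrum.total_intensity == pytest.approx(
                before.spectrum.total_intensity
            )


class TestTruePairs:
    def test_one_to_one_enforced(self):
        with pytest.raises(ValueError):
            TruePairSet([(0, 1), (0, 2)])
        with pytest.raises(ValueError):
            TruePairSet([(1, 0), (2, 0)])

    def test_round_trip(self, tmp_path):
        truth = TruePairSet([(0, 3), (2, 1), (5, 5)])
        f = tmp_path / "truth.csv"
        write_true_pairs(truth, f)
        assert read_true_pairs(f).pairs == truth.pairs
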