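"""Peak processing: parsing, calibration, filtering and ±5 % binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arisa import (
    Fingerprint,
    PeakRecord,
    Platform,
    PlatformModel,
    SizeWindow,
    band_richness,
    bin_peaks,
    calibrate_sizes,
    filter_peaks,
    read_bin_table,
    read_peak_tables,
    write_bin_table,
)
from arisa.peaks import optimal_partition
from conftest import brute_force_binning, all_set_partitions


def fp(sample, sizes_areas, platform=Platform.GA, heights=None):
    peaks = [
        PeakRecord(size=s, height=(heights[i] if heights else a), area=a)
        for i, (s, a) in enumerate(sizes_areas)
    ]
    return Fingerprint(sample_label=sample, platform=platform, peaks=tuple(peaks))


class TestReadPeakTables:
    def test_roundtrip_of_fixture_set(self, fixture_dir):
        fps = read_peak_tables(sorted(fixture_dir.glob("peaks_*.csv")))
        assert len(fps) == 18
        keys = {(f.sample_label, f.platform) for f in fps}
        assert len(keys) == 18

    def test_negative_area_names_row(self, tmp_path):
        path = tmp_path / "peaks_ga_bad.csv"
        path.write_text(
            "sample,platform,size_bp,height,area,is_standard\n"
            "bad,ga,500,100,200,False\n"
            "bad,ga,600,100,-5,False\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_peak_tables([path])

    def test_empty_file_with_header_gives_empty_fingerprint(self, tmp_path):
        path = tmp_path / "peaks_mf_lane0.csv"
        path.write_text("sample,platform,size_bp,height,area,is_standard\n")
        fps = read_peak_tables([path])
        assert len(fps) == 1
        assert fps[0].sample_label == "lane0"
        assert fps[0].platform is Platform.MF
        assert fps[0].peaks == ()

    def test_missing_column_and_unknown_platform(self, tmp_path):
        p1 = tmp_path / "peaks_ga_x.csv"
        p1.write_text("sample,platform,size_bp,height\nx,ga,500,10\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_peak_tables([p1])
        p2 = tmp_path / "peaks_ga_y.csv"
        p2.write_text(
            "sample,platform,size_bp,height,area,is_standard\ny,solexa,500,10,10,False\n"
        )
        with pytest.raises(ValueError, match="platform"):
            read_peak_tables([p2])


class TestCalibration:
    def test_identity_calibration(self):
        f = Fingerprint(
            "s",
            Platform.MF,
            (
                PeakRecord(15, 1000, 2000, is_standard=True),
                PeakRecord(600, 50, 100),
                PeakRecord(1500, 1000, 2000, is_standard=True),
            ),
        )
        out = calibrate_sizes(f, [15, 1500])
        assert [p.size for p in out.peaks] == [pytest.approx(600.0)]
        assert not any(p.is_standard for p in out.peaks)

    def test_inverts_linear_distortion_exactly(self):
        true_sizes = [440.0, 652.0, 910.0]
        scale, offset = 1.1, 7.0
        peaks = [PeakRecord(scale * s + offset, 50, 100) for s in true_sizes]
        stds = [PeakRecord(scale * s + offset, 1000, 2000, is_standard=True) for s in (15, 1500)]
        f = Fingerprint("s", Platform.MF, tuple(peaks + stds))
        out = calibrate_sizes(f, [15, 1500])
        assert [p.size for p in out.peaks] == pytest.approx(true_sizes)

    def test_piecewise_map_with_ladder(self):
        # nonlinear distortion sampled at ladder points is undone at those points
        ladder = [100.0, 200.0, 400.0, 800.0]
        distort = lambda x: x + 0.05 * x**1.1
        stds = [PeakRecord(distort(s), 1000, 2000, is_standard=True) for s in ladder]
        sample = [PeakRecord(distort(200.0), 50, 100)]
        f = Fingerprint("s", Platform.GA, tuple(sample + stds))
        out = calibrate_sizes(f, ladder)
        assert out.peaks[0].size == pytest.approx(200.0)

    def test_requires_two_standards(self):
        f = fp("s", [(600, 100)])
        with pytest.raises(ValueError, match="standards"):
            calibrate_sizes(f, [15, 1500])

    def test_coincident_standards_rejected(self):
        # peaks are kept size-sorted, so a degenerate ladder shows up as
        # coincident standard observations, which have no invertible map
        stds = (
            PeakRecord(100, 1, 1, is_standard=True),
            PeakRecord(100, 1, 1, is_standard=True),
        )
        f = Fingerprint("s", Platform.GA, stds)
        with pytest.raises(ValueError, match="monotone"):
            calibrate_sizes(f, [15, 1500])

    def test_mismatched_standard_count_rejected(self):
        stds = tuple(PeakRecord(s, 1, 1, is_standard=True) for s in (100, 500, 900))
        f = Fingerprint("s", Platform.GA, stds)
        with pytest.raises(ValueError, match="standards"):
            calibrate_sizes(f, [15, 1500])


class TestFilterPeaks:
    def test_mf_threshold_is_strictly_greater_than(self):
        model = PlatformModel(platform=Platform.MF, baseline=10.0, detection_threshold=20.0)
        f = fp(
            "s",
            [(500, 100), (600, 100), (700, 100)],
            platform=Platform.MF,
            heights=[30.0, 30.0001, 29.0],
        )
        out = filter_peaks(f, model)
        assert [p.size for p in out.peaks] == [600]

    def test_window_drops_short_amplicons(self):
        model = PlatformModel(platform=Platform.GA, detection_threshold=200.0)
        f = fp("s", [(350, 5000), (500, 5000), (1100, 5000)], heights=[5000, 5000, 5000])
        out = filter_peaks(f, model, SizeWindow(400, 1000))
        assert [p.size for p in out.peaks] == [500]

    def test_all_below_threshold_gives_empty_fingerprint(self):
        model = PlatformModel(platform=Platform.GA, detection_threshold=200.0)
        f = fp("s", [(500, 10), (600, 20)], heights=[10, 20])
        out = filter_peaks(f, model)
        assert out.peaks == ()

    def test_standards_never_retained(self):
        model = PlatformModel(platform=Platform.GA, detection_threshold=0.0)
        f = Fingerprint(
            "s", Platform.GA, (PeakRecord(500, 1e6, 1e6, is_standard=True), PeakRecord(600, 300, 300))
        )
        out = filter_peaks(f, model)
        assert [p.size for p in out.peaks] == [600]


class TestBinPeaks:
    def test_within_five_percent_shares_a_bin(self):
        table = bin_peaks([fp("a", [(600, 10)]), fp("b", [(620, 10)])])
        assert len(table.bin_centers) == 1

    def test_beyond_five_percent_splits(self):
        table = bin_peaks([fp("a", [(600, 10)]), fp("b", [(640, 10)])])
        assert len(table.bin_centers) == 2

    def test_abundance_is_area_fraction(self):
        table = bin_peaks([fp("a", [(500, 30), (700, 10)])])
        assert table.abundance[0].tolist() == pytest.approx([0.75, 0.25])

    def test_multiple_peaks_in_one_bin_sum_areas(self):
        table = bin_peaks([fp("a", [(600, 10), (605, 10), (700, 20)])])
        assert len(table.bin_centers) == 2
        assert table.abundance[0].tolist() == pytest.approx([0.5, 0.5])

    def test_mixed_platforms_refused(self):
        with pytest.raises(ValueError, match="platform"):
            bin_peaks([fp("a", [(600, 10)], Platform.GA), fp("b", [(600, 10)], Platform.MF)])

    def test_bin_center_is_area_weighted_mean(self):
        table = bin_peaks([fp("a", [(600, 30)]), fp("b", [(620, 10)])])
        assert table.bin_centers[0] == pytest.approx((600 * 30 + 620 * 10) / 40)

    def test_empty_sample_keeps_zero_row(self):
        table = bin_peaks([fp("a", [(600, 10)]), fp("b", [])])
        assert table.abundance[1].sum() == 0.0
        assert band_richness(table) == {"a": 1, "b": 0}

    def test_order_independence(self, states, templates, platform_models):
        from conftest import run_pipeline

        fps, table = run_pipeline(states, templates, platform_models[Platform.GA])
        permuted = bin_peaks(fps[::-1])
        assert sorted(permuted.bin_centers) == pytest.approx(sorted(table.bin_centers))
        for s in table.samples:
            i, j = table.samples.index(s), permuted.samples.index(s)
            assert np.allclose(
                sorted(table.abundance[i]), sorted(permuted.abundance[j])
            )

    def test_adjacent_bins_not_mergeable(self, ga_pipeline):
        _, table = ga_pipeline
        # a valid binning never leaves two neighbouring bins that could merge
        sizes_by_bin = []
        fps, _ = ga_pipeline
        entries = sorted(p.size for f in fps for p in f.sample_peaks)
        bounds = optimal_partition(entries, table.tolerance)
        for (i1, j1), (i2, j2) in zip(bounds, bounds[1:]):
            merged_min, merged_max = entries[i1], entries[j2 - 1]
            assert merged_max > merged_min * (1 + table.tolerance)

    def test_rows_sum_to_one(self, ga_pipeline, mf_pipeline, gel_pipeline):
        for _, table in (ga_pipeline, mf_pipeline, gel_pipeline):
            sums = table.abundance.sum(axis=1)
            assert np.allclose(sums[sums > 0], 1.0, atol=1e-9)


class TestOptimalPartitionOracle:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=400.0, max_value=1000.0), min_size=1, max_size=12),
        st.floats(min_value=0.01, max_value=0.10),
    )
    def test_matches_exhaustive_contiguous_optimum(self, sizes, tol):
        bounds = optimal_partition(sizes, tol)
        s = sorted(sizes)
        spread = sum(s[j - 1] - s[i] for i, j in bounds)
        assert (len(bounds), spread) == pytest.approx(brute_force_binning(sizes, tol))
        for i, j in bounds:
            assert s[j - 1] <= s[i] * (1 + tol)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=400.0, max_value=1000.0), min_size=1, max_size=7))
    def test_contiguous_optimum_is_global_optimum(self, sizes):
        # no arbitrary set partition beats the best contiguous one
        tol = 0.05
        best_any = (len(sizes) + 1, float("inf"))
        for part in all_set_partitions(sorted(sizes)):
            if any(max(g) > min(g) * (1 + tol) for g in part):
                continue
            cand = (len(part), sum(max(g) - min(g) for g in part))
            if cand < best_any:
                best_any = cand
        contiguous = brute_force_binning(sizes, tol)
        assert contiguous[0] == best_any[0]
        assert contiguous[1] == pytest.approx(best_any[1])

    def test_non_transitive_chain_split_optimally(self):
        # greedy left-to-right would pick {100,105},{106,110} (spread 9);
        # the optimum is {100},{105,106,110} (spread 5)
        bounds = optimal_partition([100, 105, 106, 110], 0.05)
        assert bounds == [(0, 1), (1, 4)]


class TestBinTableIO:
    def test_roundtrip(self, ga_pipeline, tmp_path):
        _, table = ga_pipeline
        path = tmp_path / "bins.csv"
        write_bin_table(table, path)
        back = read_bin_table(path)
        assert back.samples == table.samples
        assert back.platform == table.platform
        assert back.tolerance == table.tolerance
        assert np.allclose(back.abundance, table.abundance, atol=1e-9)
        assert np.asarray(back.bin_centers) == pytest.approx(
            np.asarray(table.bin_centers), abs=1e-3
        )
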