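"""Histogram thresholding: peak detection, T_TH selection, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wheattherm as wt
from wheattherm.errors import ThresholdError, ValidationError
from wheattherm.segmentation import TemperatureHistogram, _find_peaks


def brute_force_otsu(hist):
    """Independent exhaustive maximization of between-class variance.

    Ties (relative 1e-9, e.g. thresholds separated by empty bins) break
    to the lowest edge, mirroring the implementation's contract."""
    centers = hist.centers
    counts = hist.counts
    variances = []
    for k in range(1, hist.n_bins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            variances.append(0.0)
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        variances.append(w0 * w1 * (m0 - m1) ** 2)
    cutoff = max(variances) * (1.0 - 1e-9)
    for k, v in enumerate(variances, start=1):
        if v >= cutoff:
            return hist.bin_edges[k]


def bimodal_frame(rng, mu1=14.0, mu2=18.4, sd=0.5, n=2000):
    half = n // 2
    values = np.concatenate([rng.normal(mu1, sd, half), rng.normal(mu2, sd, n - half)])
    return wt.ThermalFrame(values.reshape(-1, 10))


class TestHistogram:
    def test_constant_frame_single_bin(self):
        hist = wt.build_histogram(wt.ThermalFrame(np.full((3, 3), 20.0)))
        assert (hist.counts > 0).sum() == 1
        assert hist.total == 9

    def test_two_value_frame(self):
        frame = wt.ThermalFrame(np.array([[10.0, 10.0], [20.0, 20.0]]))
        hist = wt.build_histogram(frame, bin_width=1.0)
        nz = hist.counts[hist.counts > 0]
        assert list(nz) == [2, 2]

    def test_counts_conserve_valid_pixels(self, rng):
        pixels = rng.normal(20, 3, (50, 50))
        pixels[rng.random((50, 50)) < 0.1] = np.nan
        frame = wt.ThermalFrame(pixels)
        assert wt.build_histogram(frame).total == frame.n_valid

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            wt.build_histogram(wt.ThermalFrame(np.full((2, 2), np.nan)))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), width=st.sampled_from([0.05, 0.1, 0.5]))
    def test_conservation_property(self, seed, width):
        values = np.random.default_rng(seed).normal(20, 2, 400)
        hist = wt.build_histogram(wt.ThermalFrame(values.reshape(20, 20)), width)
        assert hist.total == 400
        assert (np.diff(hist.bin_edges) > 0).all()


class TestDetectPeaks:
    def test_two_well_separated_modes(self, rng):
        hist = wt.build_histogram(bimodal_frame(rng), bin_width=0.1)
        peaks = wt.detect_peaks(hist)
        assert len(peaks) == 2
        assert abs(peaks[0] - 14.0) < 0.2
        assert abs(peaks[1] - 18.4) < 0.2

    def test_single_mode(self, rng):
        values = rng.normal(16.0, 0.5, 3000)
        hist = wt.build_histogram(wt.ThermalFrame(values.reshape(-1, 10)), 0.1)
        assert len(wt.detect_peaks(hist)) == 1

    def test_monotone_counts_peak_at_last_bin(self):
        edges = 10.0 + 0.5 * np.arange(21)
        hist = TemperatureHistogram(edges, np.arange(1, 21), 0.5)
        peaks = wt.detect_peaks(hist)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(hist.centers[-1])

    def test_peaks_ascending_and_separated(self, rng):
        hist = wt.build_histogram(bimodal_frame(rng, mu2=20.0, n=4000), 0.1)
        peaks = wt.detect_peaks(hist)
        assert peaks == sorted(peaks)
        assert all(b - a >= 1.0 for a, b in zip(peaks, peaks[1:]))


class TestSelectThreshold:
    def test_mean_of_peaks_rule(self, rng):
        hist = wt.build_histogram(bimodal_frame(rng), bin_width=0.1)
        t_th, method = wt.select_threshold(hist, peaks=[14.0, 18.4])
        assert t_th == pytest.approx(16.2)
        assert method == "mean_of_peaks"

    def test_symmetric_bimodal_midpoint(self, rng):
        frame = bimodal_frame(rng, mu1=15.0, mu2=19.0, n=20_000)
        hist = wt.build_histogram(frame, 0.1)
        t_th, method = wt.select_threshold(hist)
        assert method == "mean_of_peaks"
        assert t_th == pytest.approx(17.0, abs=0.15)

    def test_unimodal_falls_back_to_otsu(self, rng):
        values = rng.normal(16.0, 1.0, 4000)
        hist = wt.build_histogram(wt.ThermalFrame(values.reshape(-1, 10)), 0.1)
        t_th, method = wt.select_threshold(hist)
        assert method == "otsu_fallback"
        assert t_th == pytest.approx(brute_force_otsu(hist))

    def test_manual_override_wins(self, rng):
        hist = wt.build_histogram(bimodal_frame(rng), 0.1)
        params = wt.SegmentationParams(manual_threshold=16.0)
        assert wt.select_threshold(hist, params=params) == (16.0, "manual")

    def test_three_modes_keep_two_most_prominent(self, rng):
        # large modes at 14 and 20, small interloper at 17
        values = np.concatenate([rng.normal(14, 0.4, 4000),
                                 rng.normal(17, 0.3, 600),
                                 rng.normal(20, 0.4, 4000)])
        hist = wt.build_histogram(wt.ThermalFrame(values.reshape(-1, 10)), 0.1)
        temps, _ = _find_peaks(hist, 5, 0.05, 1.0)
        assert len(temps) >= 3
        t_th, method = wt.select_threshold(hist)
        assert method == "mean_of_peaks"
        assert t_th == pytest.approx(17.0, abs=0.3)

    def test_single_bin_histogram_undefined(self):
        hist = wt.build_histogram(wt.ThermalFrame(np.full((3, 3), 20.0)))
        with pytest.raises(ThresholdError):
            wt.select_threshold(hist)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_otsu_equals_brute_force(self, seed):
        r = np.random.default_rng(seed)
        values = np.concatenate([r.normal(15, r.uniform(0.3, 2.0), r.integers(50, 500)),
                                 r.normal(r.uniform(16, 25), 1.0, r.integers(50, 500))])
        hist = wt.build_histogram(wt.ThermalFrame(values.reshape(1, -1)), 0.1)
        if hist.n_bins < 2:
            return
        assert wt.otsu_threshold(hist) == pytest.approx(brute_force_otsu(hist))

    def test_otsu_matches_skimage_on_raw_values(self, rng):
        """Cross-check against an independent Otsu implementation."""
        skimage_filters = pytest.importorskip("skimage.filters")
        values = np.concatenate([rng.normal(15, 0.8, 3000), rng.normal(21, 1.0, 3000)])
        hist = wt.build_histogram(wt.ThermalFrame(values.reshape(-1, 10)), 0.05)
        ours = wt.otsu_threshold(hist)
        theirs = skimage_filters.threshold_otsu(values, nbins=hist.n_bins)
        assert ours == pytest.approx(theirs, abs=2 * 0.05)


class TestClassifyPixels:
    def test_four_pixel_example(self):
        frame = wt.ThermalFrame(np.array([[14.0, 14.0], [18.0, 18.0]]))
        seg = wt.classify_pixels(frame, 16.0)
        assert (seg.p_w, seg.p_s) == (2, 2)
        assert seg.t_w_mean == 14.0 and seg.t_s_mean == 18.0

    def test_all_below_threshold_gives_empty_soil(self):
        frame = wt.ThermalFrame(np.full((2, 2), 10.0))
        seg = wt.classify_pixels(frame, 16.0)
        assert seg.p_s == 0 and seg.p_w == 4
        assert np.isnan(seg.t_s_mean)

    def test_ties_go_to_wheat(self):
        frame = wt.ThermalFrame(np.array([[16.0, 17.0]]))
        seg = wt.classify_pixels(frame, 16.0)
        assert seg.p_w == 1 and seg.p_s == 1

    def test_missing_pixels_excluded(self):
        frame = wt.ThermalFrame(np.array([[14.0, np.nan], [18.0, np.nan]]))
        seg = wt.classify_pixels(frame, 16.0)
        assert seg.p_w + seg.p_s == frame.n_valid == 2

    def test_count_conservation(self, rng):
        frame = wt.ThermalFrame(rng.normal(20, 3, (37, 53)))
        for t in (-10.0, 18.0, 20.0, 50.0):
            seg = wt.classify_pixels(frame, t)
            assert seg.p_w + seg.p_s == frame.n_valid

    def test_raising_threshold_never_decreases_wheat(self, rng):
        frame = wt.ThermalFrame(rng.normal(20, 3, (30, 30)))
        counts = [wt.classify_pixels(frame, t).p_w for t in np.linspace(10, 30, 21)]
        assert counts == sorted(counts)


class TestSegmentationRecovery:
    def test_misclassification_below_one_percent(self, two_class_frame):
        frame, truth = two_class_frame
        seg = wt.segment_frame(frame)
        assert seg.method == "mean_of_peaks"
        miss = (seg.mask != truth.mask)[frame.valid_mask].mean()
        assert miss < 0.01

    def test_class_means_and_order(self, two_class_frame):
        frame, truth = two_class_frame
        seg = wt.segment_frame(frame)
        assert seg.t_w_mean < seg.t_th < seg.t_s_mean
        assert abs(seg.t_w_mean - 20.0) <= 0.1
        wci = wt.compute_wci(seg.p_w, seg.p_s)
        assert abs(wci - truth.cover_fraction) <= 0.02
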