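import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hsoct import dfm, recon
from hsoct.recon import HyperStack


def _stack(intensity, pitch_z=0.5, pitch_x=1.5, n_group=1.38):
    n_bands = intensity.shape[0]
    centers = 440.0 + 10.0 * np.arange(n_bands)
    return HyperStack(
        intensity=intensity, band_centers_nm=centers,
        pitch_z_um=pitch_z, pitch_x_um=pitch_x, n_group=n_group,
    )


BAND_CENTERS = 440.0 + 10.0 * np.arange(27)


class TestMIP:
    def test_identical_bands(self):
        img = np.random.default_rng(0).random((16, 8))
        stack = _stack(np.tile(img, (27, 1, 1)))
        assert np.array_equal(dfm.mip_across_bands(stack), img)

    def test_dominates_every_band(self):
        intensity = np.random.default_rng(1).random((27, 16, 8))
        mip = dfm.mip_across_bands(_stack(intensity))
        assert np.all(mip[None] >= intensity)


class TestWatershed:
    def test_constant_image_single_basin(self):
        with pytest.warns(UserWarning, match="constant"):
            seg = dfm.watershed_basins(np.ones((20, 20)), pixel_area_um2=1.0)
        assert seg.n_basins == 1
        assert np.all(seg.labels == 1)

    def test_two_separated_blobs_two_basins(self):
        z, x = np.mgrid[0:48, 0:48]
        img = (
            np.exp(-((z - 12.0) ** 2 + (x - 12.0) ** 2) / 18.0)
            + np.exp(-((z - 36.0) ** 2 + (x - 36.0) ** 2) / 18.0)
        )
        seg = dfm.watershed_basins(img, pixel_area_um2=4.0, min_area_um2=8.0)
        assert seg.n_basins == 2
        assert seg.labels[12, 12] != seg.labels[36, 36]

    def test_min_area_enforced_and_exhaustive(self, phantom_analysis):
        _, _, _, res = phantom_analysis
        seg = res["segmentation"]
        assert np.all(seg.areas_um2 >= 8.0)
        assert seg.labels.min() >= 1
        assert len(np.unique(seg.labels)) == seg.n_basins


class TestBasinSpectra:
    def test_uniform_bands_give_constant_spectra(self):
        intensity = np.ones((27, 12, 6)) * np.arange(1, 28)[:, None, None]
        stack = _stack(intensity)
        labels = np.arange(72).reshape(12, 6) % 4 + 1
        seg = dfm.BasinSegmentation(labels, 4, np.full(4, 18.0), 1.0)
        means = dfm.basin_spectra(stack, seg)
        assert np.allclose(means, np.arange(1, 28)[None, :])

    def test_area_weighted_means_conserve_band_totals(self, phantom_analysis):
        _, _, stack, res = phantom_analysis
        seg = res["segmentation"]
        means = dfm.basin_spectra(stack, seg)
        areas_px = np.bincount(seg.labels.ravel())[1:]
        for b in (0, 13, 26):
            total = (means[:, b] * areas_px).sum()
            assert total == pytest.approx(stack.intensity[b].sum(), rel=1e-10)

    def test_geometry_mismatch_raises(self):
        stack = _stack(np.ones((27, 12, 6)))
        seg = dfm.BasinSegmentation(np.ones((10, 6), dtype=int), 1,
                                    np.array([60.0]), 1.0)
        with pytest.raises(ValueError):
            dfm.basin_spectra(stack, seg)


class TestDeviationAndDFM:
    def test_constant_spectrum_zero_everywhere(self):
        dev = dfm.deviation_spectrum(np.full(27, 3.7))
        assert np.allclose(dev, 0.0)
        assert dfm.dfm(dev, BAND_CENTERS) == pytest.approx(0.0, abs=1e-9)

    def test_mean_plus_pattern_recovers_pattern(self):
        pattern = np.cos(np.linspace(0, 6 * np.pi, 27))
        pattern -= pattern.mean()
        dev = dfm.deviation_spectrum(5.0 + pattern)
        assert np.allclose(dev, pattern, atol=1e-12)

    def test_unit_deviation_integrates_to_260(self):
        assert dfm.dfm(np.ones(27), BAND_CENTERS) == pytest.approx(260.0)

    def test_ramp_integrates_to_130(self):
        ramp = np.linspace(0.0, 1.0, 27)
        assert dfm.dfm(ramp, BAND_CENTERS) == pytest.approx(130.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        spectrum=arrays(np.float64, 27,
                        elements=st.floats(0.0, 1e6, allow_nan=False)),
        alpha=st.floats(1e-3, 1e3),
    )
    def test_positively_homogeneous_and_zero_mean(self, spectrum, alpha):
        dev = dfm.deviation_spectrum(spectrum)
        assert abs(dev.mean()) <= 1e-9 * max(1.0, np.abs(spectrum).max())
        d1 = dfm.dfm(dev, BAND_CENTERS)
        d2 = dfm.dfm(dfm.deviation_spectrum(alpha * spectrum), BAND_CENTERS)
        assert d2 == pytest.approx(alpha * d1, rel=1e-9, abs=1e-12)


class TestDFMMapOp:
    def test_single_basin_constant_map(self):
        seg = dfm.BasinSegmentation(np.ones((8, 8), dtype=int), 1,
                                    np.array([64.0]), 1.0)
        out = dfm.dfm_map(seg, np.array([2.5]))
        assert np.all(out == 2.5)

    def test_piecewise_constant_and_histogram_identity(self):
        labels = (np.arange(64).reshape(8, 8) // 16) + 1
        seg = dfm.BasinSegmentation(labels, 4, np.full(4, 16.0), 1.0)
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        out = dfm.dfm_map(seg, vals)
        for lab, v in zip(range(1, 5), vals):
            assert np.all(out[labels == lab] == v)
        binc = np.bincount(out.astype(int).ravel())[1:]
        assert np.all(binc == 16)


class TestNoiseEstimation:
    def test_constant_roi_zero_sd(self):
        img = np.ones((20, 20))
        mean, sd = dfm.estimate_noise_stats(img, np.ones_like(img, dtype=bool))
        assert sd == 0.0 and mean == 1.0

    def test_gaussian_noise_recovered(self):
        rng = np.random.default_rng(3)
        img = rng.normal(5.0, 2.0, (100, 100))
        sd = dfm.estimate_noise_sd(img, np.ones_like(img, dtype=bool))
        assert sd == pytest.approx(2.0, rel=0.10)

    def test_small_roi_raises(self):
        img = np.ones((5, 5))
        with pytest.raises(ValueError):
            dfm.estimate_noise_sd(img, np.ones_like(img, dtype=bool))


class TestSurfaceDetection:
    def _interface_image(self, rows):
        img = np.full((64, len(rows)), 1e-4)
        for ix, r in enumerate(rows):
            img[r, ix] = 1.0
            img[r + 1, ix] = 0.6
        return img

    def test_flat_interface(self):
        surf = dfm.detect_surface(self._interface_image([30] * 40))
        assert np.all(np.abs(surf - 30) <= 1)

    def test_tilted_interface(self):
        rows = [20 + ix // 4 for ix in range(40)]
        surf = dfm.detect_surface(self._interface_image(rows))
        assert np.all(np.abs(surf - np.asarray(rows)) <= 1)

    def test_median_filter_removes_outlier_column(self):
        rows = [30] * 40
        rows[17] = 5
        surf = dfm.detect_surface(self._interface_image(rows))
        assert abs(surf[17] - 30) <= 1


class TestFractionAboveThreshold:
    def test_zero_map_zero_fraction(self):
        img = np.zeros((100, 10))
        surf = np.full(10, 10.0)
        frac = dfm.fraction_above_threshold(img, surf, 1.0, 0.0, 1.0)
        assert frac == 0.0

    def test_saturated_map_full_fraction(self):
        img = np.full((100, 10), 4.0)
        surf = np.full(10, 10.0)
        frac = dfm.fraction_above_threshold(img, surf, 1.0, 0.0, 1.0, k=3.0)
        assert frac == 100.0

    def test_window_truncation_warns(self):
        img = np.zeros((30, 4))
        surf = np.full(4, 10.0)
        with pytest.warns(UserWarning, match="truncated"):
            dfm.fraction_above_threshold(img, surf, 1.0, 0.0, 1.0,
                                         window_um=50.0)


class TestRGBEncode:
    def test_identical_bands_gray(self):
        img = np.random.default_rng(0).random((16, 8))
        stack = _stack(np.tile(img, (27, 1, 1)))
        rgb = dfm.rgb_encode(stack)
        assert np.allclose(rgb[..., 0], rgb[..., 1])
        assert np.allclose(rgb[..., 1], rgb[..., 2])

    def test_band_exclusive_feature_single_channel(self):
        intensity = np.full((27, 16, 8), 1e-6)
        idx_560 = 12
        intensity[idx_560, 8, 4] = 1.0
        assert BAND_CENTERS[idx_560] == 560.0
        rgb = dfm.rgb_encode(_stack(intensity))
        assert rgb[8, 4, 0] == pytest.approx(1.0)     # red = 560 nm
        assert rgb[8, 4, 1] < 0.1 and rgb[8, 4, 2] < 0.1

    def test_missing_band_raises(self):
        stack = _stack(np.ones((27, 4, 4)))
        with pytest.raises(ValueError):
            dfm.rgb_encode(stack, bands_nm=(540.0, 550.0, 561.0))


class TestAverageRepeats:
    def test_identical_repeats_identity(self):
        stack = _stack(np.random.default_rng(0).random((27, 8, 4)))
        avg = dfm.average_repeats([stack, stack, stack])
        assert np.allclose(avg.intensity, stack.intensity)

    def test_mean_of_two(self):
        a = _stack(np.zeros((27, 4, 4)))
        b = _stack(np.ones((27, 4, 4)))
        avg = dfm.average_repeats([a, b])
        assert np.allclose(avg.intensity, 0.5)


class TestAnalyzeStack:
    def test_phantom_summary_contract(self, phantom_analysis):
        _, _, _, res = phantom_analysis
        dmap = res["dfm_map"]
        assert np.array_equal(dmap.binary, dmap.dfm_image > dmap.threshold)
        assert dmap.threshold == pytest.approx(
            dmap.noise_mean + dmap.k * dmap.noise_sd
        )
        fr = res["fraction_above_threshold"]
        assert 0.0 <= fr["dfm_pct"] <= 100.0
        assert 0.0 <= fr["intensity_pct"] <= 100.0
        table = res["basin_table"]
        assert len(table) == res["segmentation"].n_basins
        assert np.all(table["dfm"] >= 0)

    def test_interface_line_suppressed_in_dfm(self, phantom_analysis):
        """The flat-spectrum surface line stands out less in DFM than in
        intensity, relative to the granules below it."""
        scene, raw, stack, res = phantom_analysis
        surf_rows = res["surface_px"].astype(int)
        mip, dmap = res["mip"], res["dfm_map"].dfm_image
        cols = np.arange(mip.shape[1])
        surf_int = np.array([mip[surf_rows[c] - 1 : surf_rows[c] + 9, c].max()
                             for c in cols])
        surf_dfm = np.array([dmap[surf_rows[c] - 1 : surf_rows[c] + 9, c].max()
                             for c in cols])
        deep = slice(int(surf_rows.max()) + 30, None)
        contrast_int = np.median(surf_int) / mip[deep].max()
        contrast_dfm = np.median(surf_dfm) / dmap[deep].max()
        assert contrast_dfm < contrast_int
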