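import numpy as np
import pytest

from hsoct import recon, synth
from hsoct.recon import BandConfig

from conftest import reflector_column


@pytest.fixture(scope="module")
def k_grid():
    return np.linspace(8.6, 14.7, 2048)


class TestRemoveBackground:
    def test_reference_input_gives_zero(self):
        ref = np.linspace(0.5, 1.0, 64)
        assert np.allclose(recon.remove_background(ref.copy(), ref), 0.0)

    def test_normalization_algebra(self):
        ref = np.linspace(0.5, 1.0, 64)
        eps = 0.01
        phase = np.cos(np.linspace(0, 20, 64))
        raw = ref * (1.0 + eps * phase)
        out = recon.remove_background(raw, ref)
        assert np.allclose(out, eps * phase, atol=1e-14)

    def test_low_reference_pixels_masked(self):
        ref = np.ones(64)
        ref[:5] = 1e-6
        out = recon.remove_background(np.full(64, 2.0), ref)
        assert np.all(out[:5] == 0)
        assert np.allclose(out[5:], 1.0)

    def test_all_zero_reference_raises(self):
        with pytest.raises(ValueError):
            recon.remove_background(np.ones(16), np.zeros(16))


class TestResampleLinearK:
    def test_identity_for_uniform_k_input(self):
        k = np.linspace(9.0, 14.0, 512)
        lam = 2.0 * np.pi / k * 1000.0        # λ grid whose k grid is uniform
        spec = np.sin(3.0 * k) + 0.2 * np.cos(11.0 * k)
        k_out, out = recon.resample_linear_k(spec, lam, n_k=512)
        assert np.allclose(k_out, k)
        assert np.max(np.abs(out - spec)) < 1e-10

    def test_tone_sharpens_after_resampling(self):
        """A pure cosine in k, sampled uniformly in λ, transforms to a
        sharper peak after k-linearization."""
        lam = np.linspace(425.0, 735.0, 2048)
        k = 2.0 * np.pi / (lam / 1000.0)
        z = 60.0
        fringe = np.cos(2.0 * k * z)

        def peak_to_background(sig):
            mag = np.abs(np.fft.fft(sig))[: len(sig) // 2]
            pk = int(np.argmax(mag[4:])) + 4
            window = np.zeros(len(mag), dtype=bool)
            window[max(pk - 8, 0) : pk + 9] = True
            return mag[pk] / np.median(mag[~window][4:])

        before = peak_to_background(fringe)
        _, resampled = recon.resample_linear_k(fringe, lam, n_k=2048)
        after = peak_to_background(resampled)
        assert after > 5.0 * before

    def test_decreasing_calibration_equivalent(self):
        lam = np.linspace(425.0, 735.0, 256)
        spec = np.sin(np.linspace(0, 30, 256))
        k1, out1 = recon.resample_linear_k(spec, lam, n_k=256)
        k2, out2 = recon.resample_linear_k(spec[::-1], lam[::-1], n_k=256)
        assert np.allclose(k1, k2)
        assert np.allclose(out1, out2)

    def test_non_monotone_raises(self):
        lam = np.array([500.0, 520.0, 510.0, 530.0])
        with pytest.raises(ValueError):
            recon.resample_linear_k(np.ones(4), lam)


class TestBandWindows:
    def test_band_count_and_centers(self):
        cfg = BandConfig()
        assert cfg.n_bands == 27
        assert cfg.centers_nm[0] == 440.0
        assert cfg.centers_nm[-1] == 700.0
        assert np.all(np.diff(cfg.centers_nm) == 10.0)

    def test_shared_fwhm_value(self):
        # 4 ln2 / (1.38 · 6 μm)
        cfg = BandConfig()
        assert cfg.fwhm_k_per_um == pytest.approx(0.33485, abs=1e-4)

    def test_windows_unit_peak_shared_width(self, k_grid):
        cfg = BandConfig()
        W = recon.band_windows(cfg, k_grid)
        assert W.shape == (27, k_grid.size)
        # unit peak up to discrete sampling of the window centre
        assert np.allclose(W.max(axis=1), 1.0, atol=1e-3)
        # identical FWHM: count of samples above half maximum matches
        widths = (W >= 0.5).sum(axis=1)
        assert widths.max() - widths.min() <= 1

    def test_truncated_window_warns(self):
        cfg = BandConfig()
        narrow = np.linspace(9.0, 14.3, 512)  # 440 nm centre at the edge
        with pytest.warns(UserWarning, match="energy"):
            recon.band_windows(cfg, narrow)


class TestDispersionCompensation:
    def test_zero_coefficients_identity(self, k_grid):
        spec = np.sin(3.0 * k_grid)
        out = recon.compensate_dispersion(spec, 0.0, 0.0, k_grid)
        assert np.allclose(out, spec)

    def test_negated_coefficients_double_residual(self, k_grid):
        k0 = 0.5 * (k_grid[0] + k_grid[-1])
        spec = np.exp(1j * 2.0 * (k_grid - k0) ** 2)
        fixed = recon.compensate_dispersion(spec, 2.0, 0.0, k_grid)
        assert np.allclose(np.angle(fixed), 0.0, atol=1e-9)
        worse = recon.compensate_dispersion(spec, -2.0, 0.0, k_grid)
        assert np.allclose(np.angle(worse * np.exp(-4j * (k_grid - k0) ** 2)),
                           0.0, atol=1e-9)

    def test_estimate_scaling_invariant(self, noise_free_spectrometer):
        scene = synth.make_single_reflector_scene(z_um=100.0,
                                                  lateral_extent_um=24.0)
        raw = synth.simulate_bscan(
            scene, spectrometer=noise_free_spectrometer,
            dispersion=synth.DispersionModel(1.5, 0.3),
            n_ascans=16, repeats=1, seed=4,
        )
        fr = recon.remove_background(raw.spectra[:, :, 0], raw.reference)
        k, fr_k = recon.resample_linear_k(fr, raw.spectrometer.lam_nm, 2048)
        est1 = recon.estimate_dispersion(fr_k, k)
        est2 = recon.estimate_dispersion(37.0 * fr_k, k)
        assert est1 == pytest.approx(est2, abs=1e-6)

    def test_flat_image_raises(self, k_grid):
        with pytest.raises(ValueError, match="structure"):
            recon.estimate_dispersion(np.full(k_grid.size, 1e-9), k_grid)


class TestReconstructBand:
    def test_single_tone_peak_position(self):
        k = np.linspace(9.0, 14.0, 1024)
        z_opt = 80.0                       # optical-path depth, μm
        spec = np.cos(2.0 * k * z_opt)
        ascan = recon.reconstruct_band(spec.astype(complex))
        pitch = np.pi / (k[-1] - k[0])
        peak = int(np.argmax(np.abs(ascan[2:]))) + 2
        assert abs(peak * pitch - z_opt) <= pitch

    def test_parseval(self):
        k = np.linspace(9.0, 14.0, 1024)
        spec = (np.cos(2.0 * k * 55.0) * np.exp(-((k - 11.5) ** 2))).astype(complex)
        full = np.fft.fft(spec)
        assert (np.abs(full) ** 2).sum() == pytest.approx(
            1024 * (np.abs(spec) ** 2).sum(), rel=1e-10
        )


class TestPSFResolution:
    def test_all_bands_six_micron_in_tissue(self, single_reflector_stack):
        """Every sub-band reconstructs the design axial resolution."""
        scene, raw, stack = single_reflector_stack
        col = reflector_column(scene, raw)
        for b in range(stack.n_bands):
            profile = np.sqrt(stack.intensity[b][:, col])
            fwhm = recon.measure_psf_fwhm(profile, stack.pitch_z_um)
            assert fwhm / 1.38 == pytest.approx(6.0, rel=0.10)

    def test_dispersion_closed_loop_psf(self, noise_free_spectrometer):
        """Compensating with the simulator's own coefficients restores the
        dispersion-free PSF width within 5%."""
        scene = synth.make_single_reflector_scene(z_um=100.0,
                                                  lateral_extent_um=24.0)
        kwargs = dict(spectrometer=noise_free_spectrometer, n_ascans=16,
                      repeats=1, seed=2)
        raw_disp = synth.simulate_bscan(
            scene, dispersion=synth.DispersionModel(2.0, 0.5), **kwargs
        )
        raw_free = synth.simulate_bscan(scene, **kwargs)

        def full_psf_width(raw, a2, a3):
            fr = recon.remove_background(raw.spectra[:, :, 0], raw.reference)
            k, fr_k = recon.resample_linear_k(fr, raw.spectrometer.lam_nm, 2048)
            spec = recon.compensate_dispersion(fr_k, a2, a3, k)
            prof = np.abs(np.fft.fft(spec, axis=0)[4:1024, 8])
            return recon.measure_psf_fwhm(prof, np.pi / (k[-1] - k[0]))

        w_free = full_psf_width(raw_free, 0.0, 0.0)
        w_comp = full_psf_width(raw_disp, 2.0, 0.5)
        assert w_comp / w_free == pytest.approx(1.0, abs=0.05)


class TestRegistration:
    def _blob_stack(self, n_bands=5, n_z=128, n_x=8):
        z = np.arange(n_z)
        blob = np.exp(-0.5 * ((z - 60.0) / 4.0) ** 2)
        return np.tile(blob[None, :, None], (n_bands, 1, n_x))

    def test_identical_bands_zero_shift(self):
        stack = self._blob_stack()
        _, shifts = recon.register_stack(stack, reference_band=2)
        assert np.all(shifts == 0)

    def test_constructed_shift_recovered(self):
        stack = self._blob_stack()
        stack[1] = np.roll(stack[1], 3, axis=0)
        registered, shifts = recon.register_stack(stack, reference_band=2)
        assert shifts[1] == -3
        assert np.allclose(registered[1, 10:-10], stack[2, 10:-10])

    def test_interface_aligned_across_bands(self, phantom_analysis):
        """After registration the bright interface row varies ≤ 1 px."""
        scene, raw, stack, _ = phantom_analysis
        surf_px = scene.meta["surface_z_um"] * scene.n_group / stack.pitch_z_um
        rows = []
        for b in range(stack.n_bands):
            prof = stack.intensity[b].mean(axis=1)
            lo, hi = int(surf_px) - 15, int(surf_px) + 15
            rows.append(lo + int(np.argmax(prof[lo:hi])))
        assert max(rows) - min(rows) <= 1


class TestStackDeterminism:
    def test_reconstruction_deterministic(self, noise_free_spectrometer):
        scene = synth.make_single_reflector_scene(z_um=90.0,
                                                  lateral_extent_um=12.0)
        raw = synth.simulate_bscan(scene, spectrometer=noise_free_spectrometer,
                                   n_ascans=8, repeats=1, seed=3)
        s1 = recon.reconstruct_stack(raw)
        s2 = recon.reconstruct_stack(raw)
        assert np.array_equal(s1.intensity, s2.intensity)

    def test_stack_non_negative_shared_dims(self, single_reflector_stack):
        _, _, stack = single_reflector_stack
        assert np.all(stack.intensity >= 0)
        assert stack.intensity.shape[0] == 27


class TestStackIO:
    def test_tiff_round_trip(self, tmp_path, single_reflector_stack):
        _, _, stack = single_reflector_stack
        recon.save_hyperstack(stack, tmp_path / "stack")
        back = recon.load_hyperstack(tmp_path / "stack")
        assert back.intensity.shape == stack.intensity.shape
        assert np.allclose(back.intensity, stack.intensity.astype(np.float32))
        assert np.array_equal(back.band_centers_nm, stack.band_centers_nm)
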