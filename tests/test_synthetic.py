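"""Generator tests: forward-model correctness, noise statistics, spectra,
and orientation ensembles with known moments."""

import numpy as np
import pytest

from carofret import (
    EnsembleSpec,
    GroundTruth,
    SpectrumSpec,
    TimeGrid,
    sample_unit_vectors,
    simulate_orientation_ensemble,
    simulate_polarized_decays,
    simulate_spectrum,
)


class TestPolarizedDecays:
    def test_zero_anisotropy_makes_vv_equal_vh(self):
        truth = GroundTruth(intensity_components=[(1.0, 2.0)], anisotropy_r0=0.0,
                            g_true=1.0, irf_fwhm=0.0)
        h = simulate_polarized_decays(truth, TimeGrid(0, 25, 1024), noise=False)
        np.testing.assert_allclose(h["VV"].counts, h["VH"].counts, rtol=1e-12)

    def test_zero_expected_counts_give_all_zero_histograms(self):
        truth = GroundTruth(intensity_components=[(1.0, 2.0)], total_counts=0.0,
                            background_rate=0.0)
        h = simulate_polarized_decays(truth, TimeGrid(0, 25, 1024))
        for geom in ("VV", "VH", "HV", "HH"):
            assert np.all(h[geom].counts == 0)

    def test_noise_free_forward_model_reproduces_input_anisotropy(self, noise_free_mono):
        truth, h = noise_free_mono
        t = h["VV"].time_ns
        s, p = h["VV"].counts, h["VH"].counts
        r = (s - truth.g_true * p) / (s + 2 * truth.g_true * p)
        r_true = 0.35 * np.exp(-t / 2.0)
        sel = r_true > 1e-6  # avoid 0/0 comparisons in the dead tail
        np.testing.assert_allclose(r[sel], r_true[sel], rtol=1e-10)

    def test_photon_conservation_within_poisson_error(self):
        truth = GroundTruth(intensity_components=[(1.0, 3.0)], anisotropy_r0=0.3,
                            anisotropy_components=[(1.0, 1.5)], g_true=1.2,
                            total_counts=1e6, seed=11)
        h = simulate_polarized_decays(truth, TimeGrid(0, 25, 2048))
        iso_total = h["VV"].counts.sum() + 2 * truth.g_true * h["VH"].counts.sum()
        expected = 3.0 * truth.total_counts
        assert abs(iso_total - expected) < 5 * np.sqrt(expected)

    def test_detector_bias_scales_horizontal_channels(self):
        kw = dict(intensity_components=[(1.0, 2.0)], anisotropy_r0=0.2,
                  anisotropy_components=[(1.0, 1.0)], irf_fwhm=0.0)
        grid = TimeGrid(0, 20, 1024)
        h1 = simulate_polarized_decays(GroundTruth(**kw, g_true=1.0), grid, noise=False)
        h2 = simulate_polarized_decays(GroundTruth(**kw, g_true=1.25), grid, noise=False)
        np.testing.assert_allclose(h2["VH"].counts, h1["VH"].counts / 1.25, rtol=1e-12)
        np.testing.assert_allclose(h2["VV"].counts, h1["VV"].counts, rtol=1e-12)

    def test_seed_determinism_is_bit_identical(self):
        truth = GroundTruth(intensity_components=[(1.0, 2.0)], total_counts=1e5, seed=3)
        grid = TimeGrid(0, 25, 512)
        a = simulate_polarized_decays(truth, grid)
        b = simulate_polarized_decays(truth, grid)
        for geom in ("VV", "VH", "HV", "HH"):
            assert np.array_equal(a[geom].counts, b[geom].counts)

    def test_grid_shorter_than_lifetimes_rejected(self):
        truth = GroundTruth(intensity_components=[(1.0, 10.0)])
        with pytest.raises(ValueError, match="5x the longest lifetime"):
            simulate_polarized_decays(truth, TimeGrid(0, 25, 1024))

    def test_grid_shorter_than_irf_support_rejected(self):
        truth = GroundTruth(intensity_components=[(1.0, 0.05)], irf_fwhm=2.0,
                            irf_t0=0.0)
        with pytest.raises(ValueError, match="IRF support"):
            simulate_polarized_decays(truth, TimeGrid(0, 1.0, 256))

    def test_invalid_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GroundTruth(intensity_components=[(0.5, 1.0), (0.4, 2.0)])
        with pytest.raises(ValueError, match="positive"):
            GroundTruth(intensity_components=[(1.0, -1.0)])
        with pytest.raises(ValueError):
            GroundTruth(intensity_components=[(1.0, 1.0)], anisotropy_r0=0.5)


class TestSpectrumGenerator:
    def test_single_band_peaks_at_center(self):
        spec = SpectrumSpec(bands=[(570.0, 20.0, 1.0)], grid=(400, 700, 1.0))
        s = simulate_spectrum(spec)
        i = np.argmax(s.values)
        assert s.wavelength_nm[i] == 570.0
        assert s.values[i] == pytest.approx(1.0)

    def test_two_separated_bands_integrate_additively(self):
        # analytic Gaussian integral: h * sigma * sqrt(2 pi)
        bands = [(450.0, 5.0, 2.0), (650.0, 8.0, 1.0)]
        s = simulate_spectrum(SpectrumSpec(bands=bands, grid=(350, 750, 0.25)))
        expected = sum(h * w * np.sqrt(2 * np.pi) for _, w, h in bands)
        got = np.trapezoid(s.values, s.wavelength_nm)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_zero_height_bands_give_zero_spectrum(self):
        s = simulate_spectrum(SpectrumSpec(bands=[(500.0, 10.0, 0.0)]))
        assert np.all(s.values == 0)

    def test_empty_band_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            SpectrumSpec(bands=[])


class TestOrientationEnsembles:
    def test_fixed_mode_repeats_axis(self):
        spec = EnsembleSpec(mode="fixed", cone_axis=(0, 0, 1), n_frames=10)
        v = sample_unit_vectors(spec)
        assert v.shape == (10, 3)
        np.testing.assert_array_equal(v, np.tile([0, 0, 1.0], (10, 1)))

    def test_isotropic_sphere_moments(self):
        n = 1_000_000
        v = sample_unit_vectors(EnsembleSpec(mode="isotropic", n_frames=n, seed=5))
        # component means -> 0 with SE = sqrt(1/3/n); z^2 mean -> 1/3
        se_mean = np.sqrt(1.0 / 3.0 / n)
        assert np.all(np.abs(v.mean(axis=0)) < 3 * se_mean)
        z2 = v[:, 2] ** 2
        se_z2 = z2.std() / np.sqrt(n)
        assert abs(z2.mean() - 1.0 / 3.0) < 3 * se_z2
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)

    def test_zero_halfangle_cone_degenerates_to_fixed(self):
        axis = np.array([1.0, 2.0, 2.0]) / 3.0
        spec = EnsembleSpec(mode="cone", cone_axis=tuple(axis),
                            cone_halfangle=0.0, n_frames=7, seed=1)
        np.testing.assert_allclose(sample_unit_vectors(spec), np.tile(axis, (7, 1)),
                                   atol=1e-12)

    def test_cone_mode_stays_inside_cap(self):
        axis = (0.0, 1.0, 0.0)
        spec = EnsembleSpec(mode="cone", cone_axis=axis, cone_halfangle=30.0,
                            n_frames=5000, seed=9)
        v = sample_unit_vectors(spec)
        cos_t = v @ np.asarray(axis)
        assert np.all(cos_t >= np.cos(np.radians(30.0)) - 1e-12)

    def test_zero_norm_axis_rejected(self):
        with pytest.raises(ValueError, match="non-zero norm"):
            EnsembleSpec(mode="fixed", cone_axis=(0, 0, 0))

    def test_full_ensemble_is_seeded_and_unit_norm(self):
        spec = EnsembleSpec(mode="isotropic", n_frames=100, seed=2)
        a = simulate_orientation_ensemble(spec)
        b = simulate_orientation_ensemble(spec)
        np.testing.assert_array_equal(a.donor_dipole, b.donor_dipole)
        assert not np.array_equal(a.donor_dipole, a.acceptor_dipole)
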