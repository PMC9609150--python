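"""Anisotropy construction, G-factor estimation, rotational correlation
fitting and the Stokes-Einstein-Debye viscosity conversion."""

import numpy as np
import pytest

from carofret import (
    DecayHistogram,
    GroundTruth,
    TimeGrid,
    build_anisotropy,
    compute_g_factor,
    fit_rotational_correlation,
    microviscosity,
    simulate_polarized_decays,
    theta_from_viscosity,
)


def hist(t, y, geom="VV"):
    return DecayHistogram(t, y, geometry=geom)


class TestGFactor:
    def test_identical_channels_give_unity(self):
        t = np.linspace(0, 10, 256)
        y = 1000 * np.exp(-t / 3.0)
        assert compute_g_factor(hist(t, y, "HV"), hist(t, y, "HH")) == pytest.approx(1.0)

    def test_recovers_generator_bias_within_poisson_error(self):
        truth = GroundTruth(intensity_components=[(1.0, 3.0)], g_true=1.2,
                            total_counts=1e6, seed=21)
        h = simulate_polarized_decays(truth, TimeGrid(0, 25, 2048))
        g = compute_g_factor(h["HV"], h["HH"])
        n_hv, n_hh = h["HV"].counts.sum(), h["HH"].counts.sum()
        se = g * np.sqrt(1 / n_hv + 1 / n_hh)
        assert abs(g - 1.2) < 3 * se

    def test_all_zero_hh_rejected(self):
        t = np.linspace(0, 10, 256)
        with pytest.raises(ValueError, match="non-positive"):
            compute_g_factor(hist(t, np.full_like(t, 10.0), "HV"),
                             hist(t, np.zeros_like(t), "HH"))

    def test_low_count_window_rejected(self):
        t = np.linspace(0, 10, 256)
        y = np.full_like(t, 0.1)
        with pytest.raises(ValueError, match="100 counts"):
            compute_g_factor(hist(t, y, "HV"), hist(t, y, "HH"))

    def test_grid_mismatch_rejected(self):
        t1 = np.linspace(0, 10, 256)
        t2 = np.linspace(0, 12, 256)
        with pytest.raises(ValueError, match="time grid"):
            compute_g_factor(hist(t1, np.full_like(t1, 10.0)),
                             hist(t2, np.full_like(t2, 10.0)))


class TestBuildAnisotropy:
    def test_equal_channels_give_zero_anisotropy(self):
        t = np.linspace(0, 10, 512)
        y = 1e4 * np.exp(-t / 3.0)
        aniso, total = build_anisotropy(hist(t, y), hist(t, y, "VH"), g=1.0)
        assert np.allclose(aniso.r[aniso.valid_mask], 0.0, atol=1e-12)
        np.testing.assert_allclose(total.counts, 3 * y, rtol=1e-12)

    def test_zero_perpendicular_gives_unit_anisotropy(self):
        t = np.linspace(0, 10, 512)
        y = 1e4 * np.exp(-t / 3.0)
        aniso, _ = build_anisotropy(hist(t, y), hist(t, np.zeros_like(y), "VH"), g=1.0)
        assert np.allclose(aniso.r[aniso.valid_mask], 1.0, atol=1e-12)

    def test_forward_model_oracle(self, noise_free_mono):
        truth, h = noise_free_mono
        aniso, _ = build_anisotropy(h["VV"], h["VH"], truth.g_true, min_denominator=1.0)
        t = aniso.time_ns
        r_true = 0.35 * np.exp(-t / 2.0)
        sel = aniso.valid_mask & (r_true > 1e-7)
        np.testing.assert_allclose(aniso.r[sel], r_true[sel], atol=1e-8)

    def test_low_count_channels_masked_not_clamped(self, two_component_decays):
        aniso, _ = build_anisotropy(two_component_decays["VV"],
                                    two_component_decays["VH"], 1.2)
        assert not np.all(aniso.valid_mask)
        assert np.all(np.isnan(aniso.r[~aniso.valid_mask]))
        r_valid = aniso.r[aniso.valid_mask]
        assert np.all((r_valid >= -0.5) & (r_valid <= 1.0))

    def test_horizontal_rescaling_leaves_r_unchanged(self, noise_free_mono):
        truth, h = noise_free_mono
        g0 = compute_g_factor(h["HV"], h["HH"])
        c = 0.5  # horizontal-analyzer channels detected c times as efficiently
        vh = hist(h["VH"].time_ns, h["VH"].counts * c, "VH")
        hh = hist(h["HH"].time_ns, h["HH"].counts * c, "HH")
        g1 = compute_g_factor(h["HV"], hh)
        assert g1 == pytest.approx(g0 / c, rel=1e-12)
        a0, _ = build_anisotropy(h["VV"], h["VH"], g0, min_denominator=1.0)
        a1, _ = build_anisotropy(h["VV"], vh, g1, min_denominator=1.0)
        sel = a0.valid_mask & a1.valid_mask
        np.testing.assert_allclose(a1.r[sel], a0.r[sel], rtol=1e-9)

    def test_grid_mismatch_rejected(self):
        t1 = np.linspace(0, 10, 128)
        t2 = np.linspace(0, 11, 128)
        with pytest.raises(ValueError, match="time grid"):
            build_anisotropy(hist(t1, np.ones_like(t1)),
                             hist(t2, np.ones_like(t2), "VH"), 1.0)


class TestRotationalCorrelation:
    def test_noise_free_single_theta_recovered(self, noise_free_mono):
        truth, h = noise_free_mono
        aniso, _ = build_anisotropy(h["VV"], h["VH"], truth.g_true, min_denominator=10.0)
        fit, theta = fit_rotational_correlation(aniso, 1)
        assert fit.success
        assert theta == pytest.approx(2.0, rel=1e-6)
        assert fit.amplitudes.sum() == pytest.approx(0.35, rel=1e-4)

    def test_two_component_theta_is_amplitude_weighted(self):
        truth = GroundTruth(
            intensity_components=[(1.0, 5.0)],
            anisotropy_r0=0.35,
            anisotropy_components=[(0.2 / 0.35, 0.5), (0.15 / 0.35, 5.0)],
            irf_fwhm=0.0, seed=0,
        )
        h = simulate_polarized_decays(truth, TimeGrid(0, 30, 4096), noise=False)
        aniso, _ = build_anisotropy(h["VV"], h["VH"], 1.0, min_denominator=10.0)
        fit, theta = fit_rotational_correlation(aniso, 2)
        assert fit.success
        # (0.2*0.5 + 0.15*5) / 0.35
        assert theta == pytest.approx(2.4286, abs=2e-3)

    def test_flat_zero_anisotropy_flagged_as_failure(self):
        t = np.linspace(0, 10, 512)
        y = np.full_like(t, 1e4)
        aniso, _ = build_anisotropy(hist(t, y), hist(t, y, "VH"), g=1.0)
        fit, theta = fit_rotational_correlation(aniso, 1)
        assert not fit.success
        assert np.isnan(theta)

    def test_too_few_valid_channels_rejected(self):
        t = np.linspace(0, 1, 60)
        y = np.full_like(t, 5.0)  # below the denominator threshold
        aniso, _ = build_anisotropy(hist(t, y), hist(t, y, "VH"), g=1.0)
        with pytest.raises(ValueError, match="50 valid channels"):
            fit_rotational_correlation(aniso, 1)

    def test_fitted_initial_anisotropy_is_physical(self, two_component_decays):
        aniso, _ = build_anisotropy(two_component_decays["VV"],
                                    two_component_decays["VH"], 1.2)
        fit, _ = fit_rotational_correlation(aniso, 1)
        assert fit.success
        se = fit.stderr.get("a0", 0.0)
        se = se if np.isfinite(se) else 0.0
        assert fit.amplitudes.sum() <= 0.4 + 3 * se + 0.02


class TestMicroviscosity:
    def test_reference_value(self):
        assert microviscosity(1.0, 293.15, 0.5) == pytest.approx(7.73, abs=0.01)

    def test_small_theta_limit(self):
        assert microviscosity(1e-9, 293.15, 0.5) < 1e-8

    def test_round_trip_is_algebraic_inverse(self):
        theta = theta_from_viscosity(100.0, 310.0, 0.4)
        assert microviscosity(theta, 310.0, 0.4) == pytest.approx(100.0, rel=1e-12)

    def test_linearity_in_theta_and_inverse_temperature(self):
        base = microviscosity(2.0, 300.0, 0.5)
        assert microviscosity(4.0, 300.0, 0.5) == pytest.approx(2 * base, rel=1e-12)
        assert microviscosity(2.0, 600.0, 0.5) == pytest.approx(2 * base, rel=1e-12)

    @pytest.mark.parametrize("args", [(-1, 300, 0.5), (1, 0, 0.5), (1, 300, 0)])
    def test_non_positive_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            microviscosity(*args)
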