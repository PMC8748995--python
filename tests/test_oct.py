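"""Unit and property tests for the depth-profile attenuation fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octquant.oct import (
    ALineProfile,
    FitWindowError,
    NoSurfaceError,
    OCTVolume,
    OpticalPropertyMap,
    SystemConfig,
    axial_pixel_size,
    block_average,
    calibrate_confocal,
    compute_aip,
    compute_ratio_map,
    confocal_weight,
    detect_surface,
    fit_profile,
    fit_volume,
    model_profile,
    sensitivity_rolloff,
)


# ---------------------------------------------------------------------------
# confocal weighting and sensitivity roll-off
# ---------------------------------------------------------------------------

class TestConfocalWeight:
    def test_unity_at_focus(self):
        assert confocal_weight(300.0, 300.0, 120.0) == 1.0

    def test_half_maximum_one_rayleigh_range_away(self):
        assert confocal_weight(420.0, 300.0, 120.0) == pytest.approx(0.5)
        assert confocal_weight(180.0, 300.0, 120.0) == pytest.approx(0.5)

    def test_two_rayleigh_ranges(self):
        assert confocal_weight(540.0, 300.0, 120.0) == pytest.approx(0.2)

    def test_symmetric_about_focus(self):
        d = np.linspace(0, 500, 11)
        np.testing.assert_allclose(confocal_weight(300.0 + d, 300.0, 120.0),
                                   confocal_weight(300.0 - d, 300.0, 120.0))

    def test_invalid_rayleigh_range(self):
        with pytest.raises(ValueError):
            confocal_weight(100.0, 300.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(z=st.floats(-2000, 2000), zf=st.floats(0, 1000),
           zrs=st.floats(1.0, 500.0))
    def test_bounded_in_unit_interval(self, z, zf, zrs):
        w = confocal_weight(z, zf, zrs)
        assert 0.0 < w <= 1.0


class TestSensitivityRolloff:
    def test_disabled_is_identity(self, system):
        z = np.linspace(0, 1000, 7)
        np.testing.assert_array_equal(sensitivity_rolloff(z, system),
                                      np.ones(7))

    def test_unity_at_surface(self, system_rolloff):
        assert sensitivity_rolloff(0.0, system_rolloff) == 1.0

    def test_exponential_decay_constant(self, system_rolloff):
        assert sensitivity_rolloff(800.0, system_rolloff) == pytest.approx(
            np.exp(-1.0))

    def test_monotone_nonincreasing(self, system_rolloff):
        z = np.linspace(0, 2000, 50)
        h = sensitivity_rolloff(z, system_rolloff)
        assert np.all(np.diff(h) <= 0)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

class TestModelProfile:
    def test_amplitude_at_focus_without_attenuation(self, system):
        prof = model_profile(0.0, 1.5, np.array([system.zf]), system)
        assert prof.intensities[0] == pytest.approx(1.5)

    def test_beer_lambert_at_focus(self):
        # mu_b'=2, mu_s=1/mm, z = zf = 0.5 mm: R = 2 exp(-1)
        cfg = SystemConfig(zf=500.0, zrs=120.0, rolloff_decay=None)
        prof = model_profile(1.0, 2.0, np.array([500.0]), cfg)
        assert prof.intensities[0] == pytest.approx(2.0 * np.exp(-1.0),
                                                    rel=1e-12)

    def test_doubling_mu_s_doubles_log_slope(self, system, z_grid):
        z = z_grid[1:]  # avoid z = 0 only for cleanliness; any grid works
        base = confocal_weight(z, system.zf, system.zrs)
        r1 = model_profile(4.0, 1.0, z, system).intensities / base
        r2 = model_profile(8.0, 1.0, z, system).intensities / base
        s1 = np.diff(np.log(r1)) / np.diff(z)
        s2 = np.diff(np.log(r2)) / np.diff(z)
        np.testing.assert_allclose(s2 / s1, 2.0, atol=1e-10)

    def test_negative_parameters_rejected(self, system, z_grid):
        with pytest.raises(ValueError):
            model_profile(-1.0, 1.0, z_grid, system)
        with pytest.raises(ValueError):
            model_profile(1.0, -0.5, z_grid, system)


def test_axial_pixel_size_from_spectrometer():
    # 1.5 mm imaging depth over 1024/2 axial pixels
    assert round(axial_pixel_size(1500.0, 1024), 1) == 2.9


# ---------------------------------------------------------------------------
# block averaging and surface detection
# ---------------------------------------------------------------------------

class TestBlockAverage:
    def test_constant_volume_unchanged(self):
        vol = OCTVolume(np.full((6, 6, 4), 3.25), 2.9, 3.0)
        avg = block_average(vol, 9.0)
        np.testing.assert_array_equal(avg.intensities,
                                      np.full((2, 2, 4), 3.25))
        assert avg.lateral_spacing == 9.0

    def test_two_by_two_mean(self):
        data = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(2, 2, 1)
        avg = block_average(OCTVolume(data, 1.0, 1.0), 2.0)
        assert avg.intensities[0, 0, 0] == pytest.approx(2.5)

    def test_matches_bruteforce_nested_loops(self):
        rng = np.random.default_rng(11)
        data = rng.random((7, 9, 3))
        vol = OCTVolume(data, 1.0, 2.0)
        avg = block_average(vol, 6.0)  # 3 voxels per block, partials dropped
        expected = np.empty((2, 3, 3))
        for i in range(2):
            for j in range(3):
                expected[i, j] = data[3 * i:3 * i + 3,
                                      3 * j:3 * j + 3].mean(axis=(0, 1))
        np.testing.assert_allclose(avg.intensities, expected, atol=1e-12)

    def test_block_smaller_than_voxel_rejected(self):
        vol = OCTVolume(np.ones((4, 4, 2)), 2.9, 3.0)
        with pytest.raises(ValueError):
            block_average(vol, 2.0)


class TestDetectSurface:
    def test_step_profile(self):
        prof = ALineProfile([0, 0, 0, 10, 10], np.arange(5.0))
        assert detect_surface(prof, 0.2) == 3

    def test_all_zero_profile_raises(self):
        prof = ALineProfile(np.zeros(5), np.arange(5.0))
        with pytest.raises(NoSurfaceError):
            detect_surface(prof)

    def test_model_profile_surface_at_origin(self, system, z_grid):
        prof = model_profile(8.0, 1.0, z_grid, system)
        assert detect_surface(prof, system.surface_threshold_frac) == 0


# ---------------------------------------------------------------------------
# profile fitting
# ---------------------------------------------------------------------------

class TestFitProfile:
    def test_noiseless_round_trip(self, system, z_grid):
        prof = model_profile(8.0, 1.5, z_grid, system)
        res = fit_profile(prof, system)
        assert res.converged
        assert res.mu_s == pytest.approx(8.0, rel=1e-4)
        assert res.mu_b_rel == pytest.approx(1.5, rel=1e-4)

    @pytest.mark.parametrize("mu_s", [0.5, 2.0, 8.0, 20.0])
    @pytest.mark.parametrize("mu_b", [0.1, 1.0, 10.0])
    def test_round_trip_parameter_sweep(self, system_rolloff, z_grid,
                                        mu_s, mu_b):
        prof = model_profile(mu_s, mu_b, z_grid, system_rolloff)
        res = fit_profile(prof, system_rolloff)
        assert res.mu_s == pytest.approx(mu_s, rel=1e-4)
        assert res.mu_b_rel == pytest.approx(mu_b, rel=1e-4)

    def test_flat_zero_profile_raises_window_error(self, system, z_grid):
        with pytest.raises((FitWindowError, NoSurfaceError)):
            fit_profile(ALineProfile(np.zeros_like(z_grid), z_grid), system)

    @pytest.mark.parametrize("scale", [0.5, 3.0, 10.0])
    def test_scale_covariance(self, system, z_grid, scale):
        """Rescaling intensities rescales mu_b' and leaves mu_s unchanged."""
        prof = model_profile(6.0, 1.2, z_grid, system)
        scaled = ALineProfile(prof.intensities * scale, z_grid)
        res = fit_profile(scaled, system)
        assert res.mu_s == pytest.approx(6.0, rel=1e-6)
        assert res.mu_b_rel == pytest.approx(1.2 * scale, rel=1e-6)

    def test_speckle_recovery_after_block_averaging(self, system, z_grid):
        """Mean fitted mu_s approaches truth once speckle is averaged."""
        rng = np.random.default_rng(21)
        m = model_profile(5.0, 1.0, z_grid, system).intensities
        fits = []
        for _ in range(50):
            prof = (m * rng.exponential(1.0, (100, z_grid.size))).mean(axis=0)
            fits.append(fit_profile(ALineProfile(prof, z_grid), system).mu_s)
        assert np.mean(fits) == pytest.approx(5.0, rel=0.02)

    def test_bias_shrinks_with_block_averaging(self, system, z_grid):
        """Recovery bias decreases monotonically with the averaging count."""
        rng = np.random.default_rng(7)
        m = model_profile(10.0, 1.0, z_grid, system).intensities
        biases = {}
        for n_avg in (1, 25, 100):
            vals = []
            for _ in range(200):
                prof = (m * rng.exponential(1.0, (n_avg, z_grid.size))
                        ).mean(axis=0)
                vals.append(fit_profile(ALineProfile(prof, z_grid),
                                        system).mu_s)
            biases[n_avg] = abs(np.mean(vals) - 10.0)
        assert biases[1] > biases[25] > biases[100]


class TestCalibrateConfocal:
    def test_noiseless_round_trip(self, system):
        from octquant.synthetic import (LayerSpec, NOISELESS,
                                        generate_layer_phantom,
                                        generate_oct_volume)
        bundle = generate_layer_phantom([LayerSpec("ph", "grey", 29.0, 0.0)],
                                        29.0, 2.9, glm_params=(5.0, 0.0, 0.0),
                                        noise=NOISELESS)
        vol = generate_oct_volume(bundle, system, NOISELESS, depth_um=600.0)
        zf, zrs = calibrate_confocal(vol, 5.0, system)
        assert zf == pytest.approx(system.zf, rel=1e-3)
        assert zrs == pytest.approx(system.zrs, rel=1e-3)

    def test_invalid_known_mu_s(self, system):
        vol = OCTVolume(np.ones((2, 2, 100)), 2.9, 2.9)
        with pytest.raises(ValueError):
            calibrate_confocal(vol, -1.0, system)


# ---------------------------------------------------------------------------
# map-level operations
# ---------------------------------------------------------------------------

class TestFitVolume:
    def _two_band_volume(self, system, mu_lo=2.0, mu_hi=10.0, spacing=3.0):
        nz = 200
        z = np.arange(nz) * spacing
        lo = model_profile(mu_lo, 1.0, z, system).intensities
        hi = model_profile(mu_hi, 1.0, z, system).intensities
        data = np.empty((20, 20, nz))
        data[:10] = lo
        data[10:] = hi
        return OCTVolume(data, spacing, spacing)

    def test_two_band_medians_and_pitch(self, system):
        vol = self._two_band_volume(system)
        mu_s_map, mu_b_map = fit_volume(vol, system, block_lateral=30.0)
        assert mu_s_map.pixel_pitch == 30.0
        assert np.nanmedian(mu_s_map.values[:1]) == pytest.approx(2.0,
                                                                  abs=1e-3)
        assert np.nanmedian(mu_s_map.values[1:]) == pytest.approx(10.0,
                                                                  abs=1e-3)
        assert np.all(mu_b_map.values[mu_b_map.mask] > 0)

    def test_fitted_ordering_matches_truth(self, system):
        """Noiseless bands in increasing mu_s stay ordered after fitting."""
        nz, spacing = 200, 3.0
        z = np.arange(nz) * spacing
        truths = [1.0, 4.0, 8.0, 14.0]
        data = np.empty((40, 10, nz))
        for k, mu in enumerate(truths):
            data[10 * k:10 * (k + 1)] = model_profile(mu, 1.0, z,
                                                      system).intensities
        mu_s_map, _ = fit_volume(OCTVolume(data, spacing, spacing), system,
                                 30.0)
        medians = [np.nanmedian(mu_s_map.values[k]) for k in range(4)]
        assert medians == sorted(medians)
        np.testing.assert_allclose(medians, truths, rtol=1e-3)


class TestAipAndRatio:
    def test_aip_constant_volume(self):
        vol = OCTVolume(np.full((3, 4, 5), 2.0), 1.0, 1.0)
        np.testing.assert_array_equal(compute_aip(vol).values,
                                      np.full((3, 4), 2.0))

    def test_aip_single_voxel(self):
        data = np.zeros((2, 2, 8))
        data[0, 1, 3] = 4.0
        assert compute_aip(OCTVolume(data, 1, 1)).values[0, 1] == \
            pytest.approx(0.5)

    def test_aip_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        data = rng.random((4, 5, 6))
        expected = np.array([[data[i, j].mean() for j in range(5)]
                             for i in range(4)])
        np.testing.assert_allclose(compute_aip(OCTVolume(data, 1, 1)).values,
                                   expected, atol=1e-14)

    def test_ratio_identity_and_floor_masking(self):
        mu_s = OpticalPropertyMap(np.array([[2.0, 0.05], [3.0, 4.0]]),
                                  "mu_s", 30.0)
        mu_b = OpticalPropertyMap(mu_s.values.copy(), "mu_b_rel", 30.0)
        ratio = compute_ratio_map(mu_b, mu_s, floor=0.1)
        assert ratio.values[0, 0] == pytest.approx(1.0)
        assert not ratio.mask[0, 1]           # below floor: masked
        assert np.isnan(ratio.values[0, 1])   # never infinite

    def test_ratio_matches_elementwise_division(self):
        rng = np.random.default_rng(9)
        a = rng.random((6, 6)) + 0.5
        b = rng.random((6, 6)) + 0.5
        ratio = compute_ratio_map(OpticalPropertyMap(b, "mu_b_rel", 30.0),
                                  OpticalPropertyMap(a, "mu_s", 30.0), 0.1)
        np.testing.assert_allclose(ratio.values, b / a, atol=1e-14)

    def test_ratio_grid_mismatch_rejected(self):
        a = OpticalPropertyMap(np.ones((3, 3)), "mu_s", 30.0)
        b = OpticalPropertyMap(np.ones((4, 3)), "mu_b_rel", 30.0)
        with pytest.raises(ValueError):
            compute_ratio_map(b, a, 0.1)
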