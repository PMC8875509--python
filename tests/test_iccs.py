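"""Correlation surfaces, Gaussian fits, f_ICCS / d estimation, local maps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from smlm_iccs import (CorrelationSurface, LocalizationTable, RenderedImage,
                       compute_correlation, compute_iccs, correlation_direct,
                       fit_correlation, local_iccs, radial_profile,
                       render_image, simulate_dataset)
from smlm_iccs.exceptions import (ConfigurationError, DegenerateInputError,
                                  InsufficientROIError)
from smlm_iccs.validation import recovery_config, render_pair
from tests.conftest import random_image_pair


class TestCorrelationSurfaces:
    def test_fft_equals_direct_definition_small_images(self, rng):
        """FFT masked correlation reproduces the definition lag by lag."""
        for trial in range(8):
            shape = (int(rng.integers(8, 17)), int(rng.integers(8, 17)))
            a, b = random_image_pair(rng, shape)
            roi = None if trial % 2 == 0 else rng.random(shape) > 0.3
            lag = 3 if min(shape) >= 10 else 2
            fft = compute_correlation(a, b, roi=roi, max_lag=lag)
            ref = correlation_direct(a, b, roi=roi, max_lag=lag)
            ok = np.isfinite(ref.values)
            err = np.abs(fft.values[ok] - ref.values[ok]) / np.abs(ref.values[ok])
            assert np.nanmax(err) < 1e-8
            np.testing.assert_array_equal(fft.n_pixels_used, ref.n_pixels_used)

    def test_autocorrelation_symmetric_and_peaked_at_zero(self, rng):
        a, _ = random_image_pair(rng, (20, 20))
        auto = compute_correlation(a, a, max_lag=4)
        np.testing.assert_allclose(auto.values, auto.values[::-1, ::-1],
                                   atol=1e-12)
        assert auto.zero_lag_value >= np.nanmax(auto.values) - 1e-12

    def test_cross_auto_transpose_symmetry(self, rng):
        a, b = random_image_pair(rng, (16, 16))
        g12 = compute_correlation(a, b, max_lag=4)
        g21 = compute_correlation(b, a, max_lag=4)
        np.testing.assert_allclose(g12.values, g21.values[::-1, ::-1],
                                   atol=1e-12)

    def test_constant_image_gives_zero_surface(self):
        img = RenderedImage(np.full((70, 70), 3.0), 10.0, (0, 0), 50.0)
        surf = compute_correlation(img, img, max_lag=2)
        np.testing.assert_allclose(surf.values, 0.0, atol=1e-15)

    def test_zero_mean_image_degenerate(self):
        img = RenderedImage(np.zeros((70, 70)), 10.0, (0, 0), 50.0)
        with pytest.raises(DegenerateInputError):
            compute_correlation(img, img, max_lag=2)

    def test_small_roi_rejected(self, rng):
        a, b = random_image_pair(rng, (16, 16))
        roi = np.zeros((16, 16), bool)
        roi[:3, :3] = True
        with pytest.raises(InsufficientROIError):
            compute_correlation(a, b, roi=roi, max_lag=3)

    def test_mismatched_grids_rejected(self, rng):
        a, _ = random_image_pair(rng, (16, 16))
        c = RenderedImage(np.ones((8, 8)), 10.0, (0, 0), 50.0)
        with pytest.raises(ConfigurationError):
            compute_correlation(a, c, max_lag=2)


class TestCorrelationFit:
    def _model_surface(self, g0, w_px, ginf, max_lag=16, pixel_size=10.0):
        lag = np.arange(-max_lag, max_lag + 1)
        xi, eta = np.meshgrid(lag, lag)
        vals = g0 * np.exp(-(xi**2 + eta**2) / w_px**2) + ginf
        return CorrelationSurface(vals, pixel_size, "auto",
                                  np.ones_like(vals, dtype=int))

    def test_recovers_own_model_exactly(self):
        surf = self._model_surface(0.5, 4.0, 0.0)
        fit = fit_correlation(surf)
        assert fit.converged
        assert fit.g0 == pytest.approx(0.5, rel=1e-6)
        assert fit.width_nm == pytest.approx(40.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-8)

    def test_offset_recovered(self):
        surf = self._model_surface(1.2, 6.0, 0.3)
        fit = fit_correlation(surf)
        assert fit.offset == pytest.approx(0.3, rel=1e-5)

    def test_auto_width_of_rendered_points_is_twice_sigma(self):
        """Autocorrelation of sigma-width Gaussians has e^-1 radius 2*sigma."""
        cfg = recovery_config(0.0, 0.0, seed=3, loc_precision=0.0,
                              n_particles_1=1500, n_particles_2=1500)
        table, _ = simulate_dataset(cfg)
        img1, _ = render_pair(table)
        auto = compute_correlation(img1, img1, max_lag=32)
        fit = fit_correlation(auto)
        assert fit.width_nm == pytest.approx(100.0, rel=0.05)

    def test_all_zero_surface_flagged_or_zero_amplitude(self):
        surf = self._model_surface(0.0, 4.0, 0.0)
        fit = fit_correlation(surf)
        assert (not fit.converged) or abs(fit.g0) < 1e-8


class TestComputeICCS:
    def test_identical_channels_fully_colocalized(self):
        cfg = recovery_config(0.3, 0.0, seed=1, n_particles_1=400,
                              n_particles_2=400, extent=(4000.0, 4000.0))
        table, _ = simulate_dataset(cfg)
        img = render_image(table, "ch1", extent=(0, 0, 4000, 4000))
        res = compute_iccs(img, img)
        assert res.m1 == pytest.approx(1.0, abs=1e-6)
        assert res.m2 == pytest.approx(1.0, abs=1e-6)
        assert res.f_iccs == pytest.approx(1.0, abs=1e-6)
        assert res.distance_nm == 0.0
        assert res.valid

    def test_f_is_mean_of_coefficients_and_clamped_value_bounded(self, rng):
        cfg = recovery_config(0.5, 0.0, seed=2, n_particles_1=500,
                              n_particles_2=500, extent=(5000.0, 5000.0))
        table, _ = simulate_dataset(cfg)
        img1 = render_image(table, "ch1", extent=(0, 0, 5000, 5000))
        img2 = render_image(table, "ch2", extent=(0, 0, 5000, 5000))
        res = compute_iccs(img1, img2)
        assert res.f_iccs == pytest.approx(0.5 * (res.m1 + res.m2), rel=1e-12)
        assert 0.0 <= res.f_iccs_clamped <= 1.0

    def test_amplitude_density_law(self):
        """Fitted auto amplitude scales as 1/N over a 16x range."""
        counts = [250, 500, 1000, 2000, 4000]
        g0s = []
        for n in counts:
            cfg = recovery_config(0.0, 0.0, seed=7, n_particles_1=n,
                                  n_particles_2=n)
            table, _ = simulate_dataset(cfg)
            img1, _ = render_pair(table)
            g0s.append(fit_correlation(
                compute_correlation(img1, img1, max_lag=32)).g0)
        slope = np.polyfit(np.log(counts), np.log(g0s), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_monotone_in_planted_fraction(self):
        """Mean recovered fraction strictly increases with planted f."""
        means = []
        for f_true in (0.0, 0.25, 0.5, 0.75, 1.0):
            vals = []
            for seed in range(10):
                cfg = recovery_config(f_true, 0.0, seed=seed,
                                      n_particles_1=800, n_particles_2=800,
                                      extent=(5000.0, 5000.0))
                table, _ = simulate_dataset(cfg)
                img1 = render_image(table, "ch1", extent=(0, 0, 5000, 5000))
                img2 = render_image(table, "ch2", extent=(0, 0, 5000, 5000))
                vals.append(compute_iccs(img1, img2).f_iccs)
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_distance_floor_small_below_rendering_width(self):
        """Planted distances below the PSF width yield small positive d."""
        cfg = recovery_config(1.0, 20.0, seed=5)
        table, _ = simulate_dataset(cfg)
        img1, img2 = render_pair(table)
        res = compute_iccs(img1, img2, max_lag=32)
        assert 0.0 <= res.distance_nm < 50.0


class TestLocalICCS:
    def test_default_window_is_69(self):
        import inspect
        assert inspect.signature(local_iccs).parameters["window"].default == 69

    def test_uniform_sample_map_matches_global_without_trend(self):
        cfg = recovery_config(0.5, 0.0, seed=11, n_particles_1=1000,
                              n_particles_2=1000, extent=(5000.0, 5000.0))
        table, _ = simulate_dataset(cfg)
        img1 = render_image(table, "ch1", extent=(0, 0, 5000, 5000))
        img2 = render_image(table, "ch2", extent=(0, 0, 5000, 5000))
        global_f = compute_iccs(img1, img2).f_iccs
        cmap = local_iccs(img1, img2)
        assert cmap.valid.all()
        assert np.nanmean(cmap.f_map) == pytest.approx(global_f, abs=0.06)
        cols = np.broadcast_to(cmap.center_cols, cmap.f_map.shape).ravel()
        slope = np.polyfit(cols, cmap.f_map.ravel(), 1)[0]
        assert abs(slope * img1.pixels.shape[1]) < 0.2  # no spatial trend

    def test_composite_sample_shows_planted_spatial_contrast(self):
        """Left half fully paired, right half independent."""
        base = recovery_config(1.0, 0.0, seed=13, n_particles_1=500,
                               n_particles_2=500, extent=(2500.0, 5000.0))
        left, _ = simulate_dataset(base)
        right, _ = simulate_dataset(dataclasses.replace(base, f_true=0.0,
                                                        seed=14))
        shifted = right.data.copy()
        shifted["x_nm"] += 2500.0
        merged = LocalizationTable(pd.concat([left.data, shifted],
                                             ignore_index=True), n_frames=1000)
        img1 = render_image(merged, "ch1", extent=(0, 0, 5000, 5000))
        img2 = render_image(merged, "ch2", extent=(0, 0, 5000, 5000))
        cmap = local_iccs(img1, img2)
        f_left = np.nanmean(cmap.f_map[:, cmap.center_cols < 250])
        f_right = np.nanmean(cmap.f_map[:, cmap.center_cols >= 260])
        assert f_left - f_right > 0.5

    def test_window_larger_than_image_rejected(self, rng):
        a, b = random_image_pair(rng, (50, 50))
        with pytest.raises(ConfigurationError):
            local_iccs(a, b, window=69)

    def test_even_window_rejected(self, rng):
        a, b = random_image_pair(rng, (100, 100))
        with pytest.raises(ConfigurationError):
            local_iccs(a, b, window=68)


def test_radial_profile_decreases_for_auto(rng):
    cfg = recovery_config(0.0, 0.0, seed=9, n_particles_1=500,
                          n_particles_2=500, extent=(5000.0, 5000.0))
    table, _ = simulate_dataset(cfg)
    img1 = render_image(table, "ch1", extent=(0, 0, 5000, 5000))
    auto = compute_correlation(img1, img1, max_lag=16)
    r_nm, g = radial_profile(auto)
    assert r_nm[0] < r_nm[-1]
    assert g[0] == max(g)
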