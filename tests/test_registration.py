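"""Landmark transforms, foci segmentation, mask transfer, masked ICCS."""

import numpy as np
import pytest

from smlm_iccs import (Mask, RenderedImage, Transform2D, compute_iccs,
                       estimate_transform_2d, masked_iccs, match_landmarks,
                       segment_foci, simulate_confocal, transfer_mask)
from smlm_iccs.exceptions import (ConditioningError, ConfigurationError,
                                  DegenerateInputError)
from smlm_iccs.validation import recovery_config, render_pair
from smlm_iccs.simulate import simulate_dataset


def _similarity(angle_deg, scale, shift):
    th = np.deg2rad(angle_deg)
    a = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return Transform2D("similarity", np.column_stack([a, shift]))


class TestTransforms:
    def test_identity_from_identical_points(self, rng):
        pts = rng.uniform(0, 10_000, (5, 2))
        tf = estimate_transform_2d(pts, pts, model="similarity")
        np.testing.assert_allclose(tf.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-9)
        assert tf.rms_residual < 1e-9

    def test_known_similarity_recovered_noiselessly(self, rng):
        true = _similarity(7.0, 1.02, (120.0, -80.0))
        src = rng.uniform(0, 10_000, (4, 2))
        tf = estimate_transform_2d(src, true.apply(src), model="similarity")
        np.testing.assert_allclose(tf.matrix, true.matrix, atol=1e-9)
        assert tf.rms_residual < 1e-9

    def test_residual_matches_dof_corrected_noise(self, rng):
        """Point RMS residual ~ sigma*sqrt(2)*sqrt(1 - k/2n), k=4 DOF.

        Per-coordinate residual variance is sigma^2*(1 - k/2n); the
        reported residual is the 2D point distance, hence the sqrt(2).
        """
        sigma, n = 20.0, 4
        true = _similarity(3.0, 0.98, (-50.0, 30.0))
        ratios = []
        for _ in range(100):
            src = rng.uniform(0, 10_000, (n, 2))
            dst = true.apply(src) + rng.normal(0, sigma, (n, 2))
            ratios.append(estimate_transform_2d(src, dst).rms_residual)
        expected = sigma * np.sqrt(2) * np.sqrt(1 - 4 / (2 * n))
        assert np.sqrt(np.mean(np.square(ratios))) == pytest.approx(expected,
                                                                    rel=0.1)

    def test_affine_needs_three_noncollinear_points(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises((ConditioningError, ConfigurationError)):
            estimate_transform_2d(src, src + 1.0, model="affine")
        with pytest.raises(ConfigurationError):
            estimate_transform_2d(src[:2], src[:2], model="affine")

    def test_inverse_round_trip(self, rng):
        tf = _similarity(11.0, 1.05, (200.0, -40.0))
        pts = rng.uniform(0, 5000, (7, 2))
        np.testing.assert_allclose(tf.inverse().apply(tf.apply(pts)), pts,
                                   atol=1e-9)

    def test_save_load_round_trip(self, tmp_path):
        tf = _similarity(2.0, 1.01, (10.0, 20.0))
        tf.rms_residual = 1.5
        tf.save(tmp_path / "t.json")
        back = Transform2D.load(tmp_path / "t.json")
        np.testing.assert_allclose(back.matrix, tf.matrix)
        assert back.model == tf.model

    def test_mutual_nearest_neighbour_matching(self, rng):
        src = rng.uniform(0, 10_000, (6, 2))
        true = _similarity(1.0, 1.0, (300.0, -200.0))
        dst = true.apply(src)
        perm = rng.permutation(6)
        ms, md = match_landmarks(src, dst[perm])
        assert len(ms) == 6
        tf = estimate_transform_2d(ms, md)
        assert tf.rms_residual < 1e-6


class TestSegmentation:
    def test_five_bright_discs_recovered(self, rng):
        img = np.full((100, 100), 10.0)
        centers = [(20, 20), (20, 80), (50, 50), (80, 20), (80, 80)]
        yy, xx = np.mgrid[:100, :100]
        for cy, cx in centers:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 16] = 100.0
        img += rng.normal(0, 1.0, img.shape)
        mask = segment_foci(img, min_area=10)
        from skimage import measure
        assert measure.label(mask.pixels).max() == 5

    def test_noise_only_image_empty_mask(self, rng):
        img = rng.normal(100.0, 1.0, (64, 64))
        with pytest.warns(UserWarning, match="empty mask"):
            mask = segment_foci(img, min_area=5000)
        assert mask.n_set == 0

    def test_border_touching_component_retained(self):
        img = np.zeros((50, 50))
        img[0:6, 10:16] = 10.0
        mask = segment_foci(img, min_area=10)
        assert mask.pixels[0, 12]

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            segment_foci(np.ones((32, 32)))

    def test_synthetic_confocal_end_to_end(self):
        centers = np.array([[1000.0, 1000.0], [3000.0, 1500.0],
                            [2000.0, 3000.0], [800.0, 3200.0],
                            [3200.0, 3200.0]])
        conf = simulate_confocal(centers, (4000.0, 4000.0),
                                 focus_radius=300.0, seed=4)
        mask = segment_foci(conf, min_area=10)
        from skimage import measure
        assert measure.label(mask.pixels).max() == 5


class TestMaskTransfer:
    def _target(self, shape=(100, 100), pixel_size=10.0):
        return RenderedImage(np.zeros(shape), pixel_size, (0.0, 0.0), 50.0)

    def test_identity_same_grid_unchanged(self, rng):
        pix = rng.random((100, 100)) > 0.6
        mask = Mask(pix, 10.0, (0.0, 0.0))
        out = transfer_mask(mask, Transform2D.identity(), self._target())
        np.testing.assert_array_equal(out.pixels, pix)

    def test_integer_pixel_translation_exact(self):
        pix = np.zeros((100, 100), bool)
        pix[40:60, 30:50] = True
        mask = Mask(pix, 10.0, (0.0, 0.0))
        tf = Transform2D("translation",
                         np.array([[1.0, 0, 70.0], [0, 1.0, -30.0]]))
        out = transfer_mask(mask, tf, self._target())
        np.testing.assert_array_equal(out.pixels[37:57, 37:57],
                                      pix[40:60, 30:50])
        assert out.n_set == mask.n_set

    def test_rotation_conserves_area_within_resampling_tolerance(self):
        pix = np.zeros((200, 200), bool)
        pix[60:140, 60:80] = True   # L-shape
        pix[120:140, 60:140] = True
        mask = Mask(pix, 10.0, (0.0, 0.0))
        center = np.array([1000.0, 1000.0])
        rot = _similarity(90.0, 1.0, (0.0, 0.0))
        shift = center - rot.apply(center)[0]
        tf = Transform2D("similarity",
                         np.column_stack([rot.matrix[:, :2], shift]))
        out = transfer_mask(mask, tf, self._target((200, 200)))
        assert out.n_set == pytest.approx(mask.n_set, rel=0.02)

    def test_mask_mapped_outside_warns_empty(self):
        pix = np.zeros((50, 50), bool)
        pix[10:20, 10:20] = True
        mask = Mask(pix, 10.0, (0.0, 0.0))
        tf = Transform2D("translation",
                         np.array([[1.0, 0, 1e6], [0, 1.0, 1e6]]))
        with pytest.warns(UserWarning, match="outside"):
            out = transfer_mask(mask, tf, self._target())
        assert out.n_set == 0


class TestMaskedICCS:
    def test_full_frame_mask_identical_to_unmasked(self):
        cfg = recovery_config(0.5, 0.0, seed=21, n_particles_1=600,
                              n_particles_2=600, extent=(5000.0, 5000.0))
        table, _ = simulate_dataset(cfg)
        from smlm_iccs import render_image
        img1 = render_image(table, "ch1", extent=(0, 0, 5000, 5000))
        img2 = render_image(table, "ch2", extent=(0, 0, 5000, 5000))
        mask = Mask(np.ones(img1.pixels.shape, bool), img1.pixel_size,
                    img1.origin)
        res_masked = masked_iccs(img1, img2, mask, max_lag=16)
        res_plain = compute_iccs(img1, img2, max_lag=16)
        assert res_masked.f_iccs == res_plain.f_iccs  # bit-identical
        assert res_masked.distance_nm == res_plain.distance_nm
        assert res_masked.m1 == res_plain.m1

    def test_empty_region_mask_degenerate(self):
        img = RenderedImage(np.zeros((100, 100)), 10.0, (0.0, 0.0), 50.0)
        img.pixels[:10, :10] = 1.0
        mask = Mask(np.zeros((100, 100), bool), 10.0, (0.0, 0.0))
        mask.pixels[50:, 50:] = True  # covers only empty space
        other = RenderedImage(img.pixels.copy(), 10.0, (0.0, 0.0), 50.0)
        with pytest.raises(DegenerateInputError):
            masked_iccs(img, other, mask, max_lag=10)

    def test_geometry_mismatch_rejected(self):
        img = RenderedImage(np.ones((50, 50)), 10.0, (0.0, 0.0), 50.0)
        mask = Mask(np.ones((50, 50), bool), 70.0, (0.0, 0.0))
        with pytest.raises(ConfigurationError):
            masked_iccs(img, img, mask)
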