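"""Block matching, trimmed transform estimation and pyramid registration."""

import numpy as np
import pytest

from slicemapper import (BlockMatchConfig, BlockPairSet,
                         InsufficientMatchesError, PlaneImage, SingularFitError,
                         Transform2D, block_correlation, center_images,
                         estimate_transform, make_experimental_slice,
                         match_blocks, register)
from slicemapper.blockmatch import _displacement_order


class TestBlockCorrelation:
    def test_self_correlation_is_one(self, rng):
        p = rng.random((4, 4))
        assert block_correlation(p, p) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self, rng):
        p = rng.random((4, 4))
        assert block_correlation(p, -p + 3.0) == pytest.approx(-1.0)

    def test_affine_intensity_invariance(self, rng):
        p = rng.random((4, 4))
        assert block_correlation(p, 2.5 * p + 0.7) == pytest.approx(1.0)

    def test_constant_patch_is_undefined(self, rng):
        assert np.isnan(block_correlation(np.ones((4, 4)), rng.random((4, 4))))


class TestDisplacementOrder:
    def test_smallest_magnitude_first(self):
        d = _displacement_order(2)
        mags = (d ** 2).sum(axis=1)
        assert np.all(np.diff(mags) >= 0)
        assert tuple(d[0]) == (0, 0)


class TestMatchBlocks:
    def test_identity_match_gives_zero_displacement(self, atlas_small):
        img = atlas_small.template(10)
        pairs = match_blocks(img, img, BlockMatchConfig())
        np.testing.assert_array_equal(pairs.ref_points, pairs.test_points)
        assert np.all(pairs.cc > 0.99)

    def test_known_shift_matches_brute_force_oracle(self, atlas_small):
        ref = atlas_small.template(10)
        shifted = PlaneImage(np.roll(ref.pixels, (5, -3), axis=(0, 1)),
                             ref.pixel_size)
        pairs = match_blocks(ref, shifted, BlockMatchConfig())
        disp = (pairs.test_points - pairs.ref_points) / ref.pixel_size[0]
        vals, counts = np.unique(np.round(disp).astype(int), axis=0,
                                 return_counts=True)
        modal = tuple(vals[counts.argmax()])
        # brute-force oracle: best integer shift by whole-image correlation
        best, best_cc = None, -2
        a = ref.pixels
        b = shifted.pixels
        for dy in range(-5, 6):
            for dx in range(-5, 6):
                rolled = np.roll(b, (-dy, -dx), axis=(0, 1))
                cc = block_correlation(a[8:-8, 8:-8], rolled[8:-8, 8:-8])
                if cc > best_cc:
                    best, best_cc = (dy, dx), cc
        assert modal == best == (5, -3)

    def test_blank_test_image_raises(self, atlas_small):
        blank = PlaneImage(np.zeros((64, 64)), 25.0)
        with pytest.raises(InsufficientMatchesError):
            match_blocks(blank, blank, BlockMatchConfig())

    def test_config_validation(self):
        with pytest.raises(Exception):
            BlockMatchConfig(trim_fraction=0.3)
        with pytest.raises(Exception):
            BlockMatchConfig(block_size=2)


class TestEstimateTransform:
    def _pairs(self, P, Q):
        return BlockPairSet(ref_points=P, test_points=Q, cc=np.ones(len(P)))

    def test_exact_rigid_recovered(self, rng):
        P = rng.uniform(-1000, 1000, (40, 2))
        T = Transform2D.rigid(10.0, (150.0, -80.0))
        est = estimate_transform(self._pairs(P, T(P)), "rigid")
        np.testing.assert_allclose(est.linear, T.linear, atol=1e-6)
        np.testing.assert_allclose(est.offset, T.offset, atol=1e-6)

    def test_affine_with_gross_outliers(self, rng):
        P = rng.uniform(-1000, 1000, (60, 2))
        T = Transform2D.affine([[1.1, 0.15], [0.0, 0.9]], (50.0, 20.0))
        Q = T(P)
        n_out = 18  # 30% gross outliers
        Q[:n_out] += rng.uniform(300, 800, (n_out, 2)) * rng.choice([-1, 1], (n_out, 2))
        est = estimate_transform(self._pairs(P, Q), "affine", trim_fraction=0.6)
        np.testing.assert_allclose(est.linear, T.linear, atol=1e-3)
        np.testing.assert_allclose(est.offset, T.offset, atol=1e-3 * 1000)

    def test_identity_pairs_give_identity(self, rng):
        P = rng.uniform(-500, 500, (20, 2))
        est = estimate_transform(self._pairs(P, P.copy()), "affine")
        np.testing.assert_allclose(est.linear, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(est.offset, 0.0, atol=1e-6)

    def test_collinear_points_raise(self):
        P = np.stack([np.linspace(0, 100, 10), np.zeros(10)], axis=1)
        with pytest.raises(SingularFitError):
            estimate_transform(self._pairs(P, P + 5.0), "affine")


class TestRegister:
    def test_self_registration_near_identity(self, atlas60):
        img = atlas60.template(30)
        T = register(img, img, "rigid", init=center_images(img, img))
        assert np.all(np.abs(T.offset) < 0.5 * 25.0)
        assert abs(T.rotation_deg()) < 0.2

    def test_rigid_recovery_within_pixel_and_degree(self, atlas60):
        true = Transform2D.rigid(4.0, (300.0, -150.0))
        img, _ = make_experimental_slice(atlas60, 30, true)
        template = atlas60.template(30)
        est = register(img, template, "rigid", init=center_images(template, img))
        assert abs(est.rotation_deg() - 4.0) < 1.0
        assert np.all(np.abs(est.offset - true.offset) < 25.0)

    def test_affine_recovers_anisotropic_scales(self, atlas60):
        true = Transform2D.affine(np.diag([1.10, 0.95]), (100.0, 50.0))
        img, _ = make_experimental_slice(atlas60, 30, true)
        template = atlas60.template(30)
        rig = register(img, template, "rigid", init=center_images(template, img))
        full = register(img, template, "affine", init=rig)
        np.testing.assert_allclose(sorted(full.scales()), [0.95, 1.10],
                                   rtol=0.02)

    def test_model_nesting_affine_on_rigid_data(self, atlas60):
        true = Transform2D.rigid(3.0, (200.0, 100.0))
        img, _ = make_experimental_slice(atlas60, 25, true)
        template = atlas60.template(25)
        rig = register(img, template, "rigid", init=center_images(template, img))
        full = register(img, template, "affine", init=rig)
        np.testing.assert_allclose(full.scales(), 1.0, rtol=0.02)

    def test_deterministic_bit_identical(self, atlas60):
        img, _ = make_experimental_slice(atlas60, 40, Transform2D.rigid(3.0))
        template = atlas60.template(40)
        init = center_images(template, img)
        a = register(img, template, "rigid", init=init)
        b = register(img, template, "rigid", init=init)
        assert np.array_equal(a.linear, b.linear)
        assert np.array_equal(a.offset, b.offset)

    def test_monotone_refinement_of_inlier_cc(self, atlas60):
        img, _ = make_experimental_slice(atlas60, 30,
                                         Transform2D.rigid(4.0, (300.0, -150.0)))
        template = atlas60.template(30)
        _, diag = register(img, template, "rigid",
                           init=center_images(template, img),
                           return_diagnostics=True)
        ccs = [d["mean_inlier_cc"] for d in diag]  # coarse -> fine
        assert all(b >= a - 1e-9 for a, b in zip(ccs, ccs[1:]))
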