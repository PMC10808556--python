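"""Image model, I/O round trips, resampling, centering and warping."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicemapper import (AlignmentError, AtlasStack, CenteringError,
                         ContractError, DegenerateImageError, FormatError,
                         LabelImage, PlaneImage, Transform2D, apply_transform,
                         center_images, compose, load_atlas, load_transform,
                         resample_to, save_atlas, save_transform)
from slicemapper.imaging import foreground_mask


def _hash(arr):
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

class TestTypes:
    def test_plane_image_rejects_nonfinite(self):
        bad = np.zeros((16, 16))
        bad[3, 3] = np.nan
        with pytest.raises(FormatError):
            PlaneImage(bad, 25.0)

    def test_plane_image_rejects_tiny(self):
        with pytest.raises(DegenerateImageError):
            PlaneImage(np.zeros((4, 16)), 25.0)

    def test_label_image_rejects_fractional(self):
        with pytest.raises(FormatError):
            LabelImage(np.full((16, 16), 0.5), 25.0)

    def test_label_image_legend_must_cover_values(self):
        lab = np.zeros((16, 16), int)
        lab[2, 2] = 7
        with pytest.raises(FormatError):
            LabelImage(lab, 25.0, legend={1: "one"})

    def test_atlas_requires_matching_lengths(self, atlas_small):
        with pytest.raises(AlignmentError):
            AtlasStack(templates=atlas_small.templates,
                       labels=atlas_small.labels[:-1], e_t=100.0)

    def test_rigid_kind_rejects_scaled_matrix(self):
        with pytest.raises(ContractError):
            Transform2D(kind="rigid", linear=1.1 * np.eye(2))


class TestTransformAlgebra:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2), min_size=18, max_size=18))
    def test_composition_associative(self, vals):
        mats = [np.asarray(vals[i:i + 6]) for i in (0, 6, 12)]
        ts = []
        for m in mats:
            lin = m[:4].reshape(2, 2) + np.eye(2)  # keep away from singular
            ts.append(Transform2D(kind="affine", linear=lin, offset=m[4:]))
        a, b, c = ts
        left = compose(compose(a, b), c)
        right = compose(a, compose(b, c))
        np.testing.assert_allclose(left.linear, right.linear, atol=1e-9)
        np.testing.assert_allclose(left.offset, right.offset, atol=1e-9)

    def test_inverse_cancels(self):
        T = Transform2D.rigid(33.0, (120.0, -45.0))
        I = compose(T, T.inverse())
        np.testing.assert_allclose(I.linear, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(I.offset, 0.0, atol=1e-9)

    def test_rigid_composition_stays_rigid(self):
        T = compose(Transform2D.rigid(10.0), Transform2D.rigid(-3.0, (5.0, 5.0)))
        assert T.kind == "rigid"
        assert abs(T.rotation_deg() - 7.0) < 1e-9

    def test_json_round_trip(self, tmp_path):
        T = Transform2D.affine([[1.05, 0.02], [-0.01, 0.97]], (310.0, -42.5))
        path = tmp_path / "t.json"
        save_transform(T, path)
        back = load_transform(path)
        assert back.kind == "affine"
        np.testing.assert_array_equal(back.linear, T.linear)
        np.testing.assert_array_equal(back.offset, T.offset)


# ---------------------------------------------------------------------------
# atlas I/O
# ---------------------------------------------------------------------------

class TestAtlasIO:
    def test_round_trip_preserves_data_and_order(self, atlas_small, tmp_path):
        tpath, lpath = tmp_path / "t.nii.gz", tmp_path / "l.nii.gz"
        save_atlas(atlas_small, tpath, lpath)
        back = load_atlas(tpath, lpath)
        assert back.n_slices == atlas_small.n_slices
        assert back.e_t == atlas_small.e_t
        for a in range(1, back.n_slices + 1):
            assert _hash(back.label(a).labels) == _hash(atlas_small.label(a).labels)
            # template intensities already in [0,1]; normalisation is identity
            np.testing.assert_allclose(back.template(a).pixels,
                                       atlas_small.template(a).pixels,
                                       atol=1e-12)

    def test_metadata_propagates(self, atlas_small, tmp_path):
        save_atlas(atlas_small, tmp_path / "t.nii", tmp_path / "l.nii")
        back = load_atlas(tmp_path / "t.nii", tmp_path / "l.nii")
        assert back.template(1).pixel_size == atlas_small.template(1).pixel_size

    def test_shape_mismatch_is_alignment_error(self, tmp_path):
        import nibabel as nib
        aff = np.diag([100.0, 25.0, 25.0, 1.0])
        nib.save(nib.Nifti1Image(np.random.rand(20, 16, 16), aff),
                 str(tmp_path / "t.nii"))
        nib.save(nib.Nifti1Image(np.zeros((19, 16, 16), dtype=np.int16), aff),
                 str(tmp_path / "l.nii"))
        with pytest.raises(AlignmentError):
            load_atlas(tmp_path / "t.nii", tmp_path / "l.nii")

    def test_noninteger_labels_is_format_error(self, tmp_path):
        import nibabel as nib
        aff = np.diag([100.0, 25.0, 25.0, 1.0])
        nib.save(nib.Nifti1Image(np.random.rand(20, 16, 16), aff),
                 str(tmp_path / "t.nii"))
        nib.save(nib.Nifti1Image(np.random.rand(20, 16, 16), aff),
                 str(tmp_path / "l.nii"))
        with pytest.raises(FormatError):
            load_atlas(tmp_path / "t.nii", tmp_path / "l.nii")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

class TestResample:
    def test_downsample_10_to_25_um(self, atlas_small):
        img = PlaneImage(atlas_small.template(10).pixels, (10.0, 10.0))
        out = resample_to(img, (25.0, 25.0))
        assert out.shape == (round(64 * 0.4), round(64 * 0.4))
        for k in range(2):
            assert abs(out.physical_extent()[k] - img.physical_extent()[k]) <= 25.0

    def test_identity_returns_same_object(self, atlas_small):
        img = atlas_small.template(1)
        assert resample_to(img, img.pixel_size) is img

    def test_labels_value_set_never_grows(self, atlas_small):
        lab = atlas_small.label(10)
        out = resample_to(lab, (40.0, 40.0))
        assert out.value_set() <= lab.value_set()

    def test_degenerate_target_raises(self, atlas_small):
        with pytest.raises(DegenerateImageError):
            resample_to(atlas_small.template(1), (1000.0, 1000.0))

    def test_there_and_back_preserves_centroid(self, atlas_small):
        img = atlas_small.template(10)
        back = resample_to(resample_to(img, (10.0, 10.0)), img.pixel_size)
        c0 = np.argwhere(foreground_mask(img)).mean(axis=0)
        c1 = np.argwhere(foreground_mask(back)).mean(axis=0)
        assert np.all(np.abs(c0 - c1) <= 1.0)


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

class TestCentering:
    def test_identical_images_give_zero(self, atlas_small):
        img = atlas_small.template(10)
        T = center_images(img, img)
        assert np.all(np.abs(T.offset) <= img.pixel_size[0] / 2)

    def test_known_shift_recovered(self, atlas_small):
        ref = atlas_small.template(10)
        shifted = PlaneImage(np.roll(ref.pixels, (8, -10), axis=(0, 1)),
                             ref.pixel_size)
        T = center_images(shifted, ref)
        # test centroid moved by (+8, -10) px at 25 µm -> (+200, -250) µm
        assert np.all(np.abs(T.offset - [200.0, -250.0]) <= 25.0)

    def test_blank_image_raises(self):
        blank = PlaneImage(np.zeros((32, 32)), 25.0, name="blank")
        with pytest.raises(CenteringError, match="blank"):
            center_images(blank, blank)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

class TestApplyTransform:
    def test_identity_nearest_bit_exact(self, atlas_small):
        lab = atlas_small.label(10)
        out = apply_transform(lab, Transform2D.identity(), "nearest")
        np.testing.assert_array_equal(out.labels, lab.labels)

    def test_rotation_preserves_label_values(self, atlas_small):
        lab = atlas_small.label(10)
        out = apply_transform(lab, Transform2D.rigid(7.3), "nearest")
        assert out.value_set() <= lab.value_set() | {0}

    def test_linear_on_labels_is_contract_error(self, atlas_small):
        with pytest.raises(ContractError):
            apply_transform(atlas_small.label(1), Transform2D.identity(),
                            "linear")

    def test_integer_translation_matches_roll_oracle(self, atlas_small):
        img = atlas_small.template(10)
        ps = img.pixel_size[0]
        # sampling at p + (3, -2) px pulls content up-left by that amount
        T = Transform2D.translation((3 * ps, -2 * ps))
        out = apply_transform(img, T, "nearest")
        oracle = np.roll(img.pixels, (-3, 2), axis=(0, 1))
        interior = (slice(4, -4), slice(4, -4))
        np.testing.assert_array_equal(out.pixels[interior], oracle[interior])

    def test_inverse_round_trip_small_interior_error(self):
        from slicemapper import PhantomSpec, make_phantom_atlas
        smooth = make_phantom_atlas(PhantomSpec(N=4, shape=(64, 64), seed=3,
                                                texture_amplitude=0.03))
        img = smooth.template(2)
        T = Transform2D.rigid(6.0, (80.0, -40.0))
        back = apply_transform(apply_transform(img, T, "linear"),
                               T.inverse(), "linear")
        b = 10
        mae = np.abs(back.pixels[b:-b, b:-b] - img.pixels[b:-b, b:-b]).mean()
        assert mae < 0.02 * np.ptp(img.pixels)
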