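"""Preprocessing: windowing arithmetic, crop geometry, resampling,
restoration round-trips, and NIfTI I/O contracts."""
import numpy as np
import pytest

from hepaseg.grids import Mask, PreprocessRecord, Volume
from hepaseg.metrics import dice_score
from hepaseg.phantom import PhantomSpec, generate_phantom
from hepaseg import preprocess as pp


@pytest.fixture(scope="module")
def phantom_case():
    return generate_phantom(PhantomSpec(seed=3))


class TestWindowNormalize:
    def test_endpoints_and_midpoint(self):
        v = Volume(np.array([[[-200.0, 200.0, 0.0, 500.0, -1000.0]]]),
                   (1, 1, 1), "HU")
        out = pp.window_normalize(v)
        np.testing.assert_allclose(out.voxels[0, 0],
                                   [0.0, 1.0, 0.5, 1.0, 0.0])
        assert out.intensity_kind == "normalized"

    def test_monotone_in_hu(self):
        hu = np.linspace(-400, 400, 81).reshape(81, 1, 1)
        out = pp.window_normalize(Volume(hu, (1, 1, 1), "HU"))
        assert np.all(np.diff(out.voxels[:, 0, 0]) >= 0)

    def test_idempotent_on_normalized(self):
        v = Volume(np.full((2, 2, 2), 0.25), (1, 1, 1), "normalized")
        assert pp.window_normalize(v) is v


class TestBodyMask:
    def test_recovers_phantom_body(self, phantom_case):
        volume, labels = phantom_case
        body = pp.compute_body_mask(volume)
        # analytic body = everything that is not air; allow a one-voxel rim
        truth = volume.voxels > -500
        assert dice_score(body.voxels, truth) > 0.98

    def test_all_air_raises(self):
        v = Volume(np.full((8, 8, 8), -1000.0), (1, 1, 1), "HU")
        with pytest.raises(ValueError, match="empty body"):
            pp.compute_body_mask(v)

    def test_all_tissue_gives_full_grid(self):
        v = Volume(np.zeros((8, 8, 8)), (1, 1, 1), "HU")
        assert pp.compute_body_mask(v).count() == 512

    def test_single_connected_component(self, phantom_case):
        from scipy import ndimage
        body = pp.compute_body_mask(phantom_case[0])
        _, n = ndimage.label(body.voxels, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_requires_hu(self):
        v = Volume(np.full((4, 4, 4), 0.5), (1, 1, 1), "normalized")
        with pytest.raises(ValueError):
            pp.compute_body_mask(v)


class TestCrop:
    def _volume_with_body(self, lo=10, hi=20, shape=(32, 32, 32)):
        g = np.zeros(shape, np.uint8)
        g[lo:hi, lo:hi, lo:hi] = 1
        vol = Volume(np.zeros(shape), (1, 1, 1), "HU")
        return vol, Mask(g, (1, 1, 1))

    def test_tight_box_margin_zero(self):
        vol, body = self._volume_with_body()
        cropped, rec = pp.crop_to_body(vol, body, margin_vox=0)
        assert cropped.shape == (10, 10, 10)
        assert rec.crop_lo == (10, 10, 10)
        assert rec.crop_hi == (20, 20, 20)

    def test_margin_arithmetic(self):
        vol, body = self._volume_with_body()
        _, rec = pp.crop_to_body(vol, body, margin_vox=2)
        assert rec.crop_lo == (8, 8, 8)
        assert rec.crop_hi == (22, 22, 22)

    def test_clipped_at_grid_edges(self):
        vol, body = self._volume_with_body(lo=0, hi=30)
        _, rec = pp.crop_to_body(vol, body, margin_vox=5)
        assert rec.crop_lo == (0, 0, 0)
        assert rec.crop_hi == (32, 32, 32)

    def test_empty_body_raises(self):
        vol = Volume(np.zeros((8, 8, 8)), (1, 1, 1), "HU")
        with pytest.raises(ValueError):
            pp.crop_to_body(vol, Mask(np.zeros((8, 8, 8), np.uint8),
                                      (1, 1, 1)), 0)


class TestResample:
    def test_halves_inplane_axes_only(self):
        v = Volume(np.zeros((64, 64, 20)), (0.8, 0.8, 2.0), "HU")
        out = pp.resample_inplane(v, 0.5)
        assert out.shape == (32, 32, 20)
        np.testing.assert_allclose(out.spacing, (1.6, 1.6, 2.0))

    def test_factor_one_is_identity(self):
        v = Volume(np.random.default_rng(0).random((8, 8, 4)), (1, 1, 1),
                   "HU")
        assert pp.resample_inplane(v, 1.0) is v

    def test_constant_volume_stays_constant(self):
        v = Volume(np.full((16, 16, 6), 7.0), (1, 1, 1), "HU")
        out = pp.resample_inplane(v, 0.5)
        np.testing.assert_allclose(out.voxels, 7.0, rtol=1e-6)

    def test_physical_extent_preserved(self):
        v = Volume(np.zeros((50, 43, 17)), (0.7, 0.9, 2.5), "HU")
        out = pp.resample_inplane(v, 0.5)
        for ax in range(2):
            before = v.shape[ax] * v.spacing[ax]
            after = out.shape[ax] * out.spacing[ax]
            assert abs(before - after) < 1e-9  # spacing recomputed exactly

    def test_invalid_factor(self):
        v = Volume(np.zeros((4, 4, 4)), (1, 1, 1), "HU")
        with pytest.raises(ValueError):
            pp.resample_inplane(v, 0.0)


class TestRestore:
    def test_identity_record_roundtrip(self):
        g = (np.random.default_rng(1).random((12, 12, 12)) < 0.3)
        m = Mask(g.astype(np.uint8), (1, 1, 1))
        rec = PreprocessRecord((12, 12, 12), (1, 1, 1), (0, 0, 0),
                               (12, 12, 12), 1.0)
        out = pp.restore_to_original(m, rec)
        assert np.array_equal(out.voxels, m.voxels)

    def test_empty_mask_restores_empty(self):
        rec = PreprocessRecord((10, 10, 10), (1, 1, 1), (2, 2, 2),
                               (8, 8, 8), 0.5)
        m = Mask(np.zeros(rec.processed_shape, np.uint8), (2, 2, 2))
        out = pp.restore_to_original(m, rec)
        assert out.shape == (10, 10, 10)
        assert out.count() == 0

    def test_shape_mismatch_raises(self):
        rec = PreprocessRecord((10, 10, 10), (1, 1, 1), (0, 0, 0),
                               (10, 10, 10), 0.5)
        with pytest.raises(ValueError):
            pp.restore_to_original(Mask(np.zeros((9, 9, 10), np.uint8),
                                        (1, 1, 1)), rec)

    def test_phantom_liver_roundtrip_dice(self):
        volume, labels = generate_phantom(PhantomSpec(seed=11))
        norm, rec, plab = pp.preprocess_case(volume, labels=labels)
        liver = Mask((plab >= 1).astype(np.uint8), norm.spacing)
        restored = pp.restore_to_original(liver, rec)
        assert dice_score(restored.voxels, labels >= 1) >= 0.95


class TestRecord:
    def test_json_roundtrip(self):
        rec = PreprocessRecord((96, 96, 64), (0.8, 0.8, 1.5), (3, 4, 5),
                               (90, 91, 60), 0.5)
        again = PreprocessRecord.from_json(rec.to_json())
        assert again == rec

    def test_invalid_box_raises(self):
        with pytest.raises(ValueError):
            PreprocessRecord((10, 10, 10), (1, 1, 1), (5, 0, 0), (4, 10, 10))


class TestNiftiIO:
    def test_roundtrip_voxels_and_spacing(self, tmp_path, phantom_case):
        volume, labels = phantom_case
        vp = tmp_path / "volume-0.nii.gz"
        sp = tmp_path / "segmentation-0.nii.gz"
        pp.write_volume(volume, vp)
        pp.write_labels(labels, volume.spacing, sp)
        vol2, lab2 = pp.read_case(vp, sp)
        np.testing.assert_allclose(vol2.voxels, volume.voxels, atol=1e-4)
        np.testing.assert_allclose(vol2.spacing, volume.spacing, rtol=1e-6)
        assert np.array_equal(lab2, labels)

    def test_anisotropic_spacing_preserved(self, tmp_path):
        v = Volume(np.zeros((6, 6, 6), np.float32), (0.7, 0.7, 2.5), "HU")
        path = tmp_path / "v.nii.gz"
        pp.write_volume(v, path)
        v2, _ = pp.read_case(path)
        np.testing.assert_allclose(v2.spacing, (0.7, 0.7, 2.5), rtol=1e-6)

    def test_bad_label_value_rejected(self, tmp_path):
        bad = np.zeros((4, 4, 4), np.uint8)
        bad[0, 0, 0] = 3
        with pytest.raises(ValueError, match="label"):
            pp.write_labels(bad, (1, 1, 1), tmp_path / "s.nii.gz")
        import nibabel as nib
        nib.save(nib.Nifti1Image(bad, np.eye(4)), str(tmp_path / "s.nii.gz"))
        pp.write_volume(Volume(np.zeros((4, 4, 4), np.float32), (1, 1, 1),
                               "HU"), tmp_path / "v.nii.gz")
        with pytest.raises(ValueError, match="label"):
            pp.read_case(tmp_path / "v.nii.gz", tmp_path / "s.nii.gz")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            pp.read_case(tmp_path / "nope.nii.gz")
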