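"""Localization stage: preprocessing geometry, crop derivation, training."""

import numpy as np
import pytest

from pericfat import locnet, nn
from pericfat.grid import EmptyMaskError, MaskGrid, VolumeGrid, bounding_box
from pericfat.phantom import PhantomSpec, generate_phantom
from tests.conftest import SMALL_SPEC

CFG = locnet.LocConfig.scaled_down()


class TestConfig:
    def test_full_scale_defaults(self):
        cfg = locnet.LocConfig()
        assert cfg.iso_spacing_mm == 3.0
        assert cfg.input_shape == (112, 112, 112)
        assert cfg.crop_shape == (384, 384, 80)
        assert cfg.safety_margin_voxels == 11
        assert cfg.lr0 == 1e-4 and cfg.lr_decay_factor == 0.5
        assert cfg.batch_size == 3 and cfg.epochs == 1200
        assert cfg.aug_translate_voxels == 10 and cfg.aug_rotate_deg == 4.0

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            locnet.LocConfig(lr_decay_factor=0.0)
        with pytest.raises(ValueError):
            locnet.LocConfig(dropout=1.0)


class TestPreprocess:
    def test_already_iso_and_sized_unchanged(self):
        data = np.full(CFG.input_shape, 40.0)
        v = VolumeGrid(data, (CFG.iso_spacing_mm,) * 3)
        out, prov = locnet.preprocess_loc(v, CFG)
        assert out.shape == CFG.input_shape
        assert out.spacing_mm == (CFG.iso_spacing_mm,) * 3
        # constant 40 HU maps to (40+1000)/2000
        np.testing.assert_allclose(out.data, 0.52, atol=1e-6)

    def test_resampling_arithmetic(self):
        # 128 mm extent at 2 mm: at 4 mm iso this is exactly 32 voxels
        v = VolumeGrid(np.zeros((64, 64, 64)), (2.0, 2.0, 2.0))
        out, prov = locnet.preprocess_loc(v, CFG)
        assert prov.iso_shape == (32, 32, 32)
        assert out.shape == CFG.input_shape

    def test_intensity_clipped_to_unit_range(self, small_phantom):
        out, _ = locnet.preprocess_loc(small_phantom.image, CFG)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_provenance_maps_center_back(self, small_phantom):
        # the center voxel of the network grid must map to within one
        # source voxel of the source-volume center
        out, prov = locnet.preprocess_loc(small_phantom.image, CFG)
        net_center = np.array(CFG.input_shape) / 2
        iso_voxel = net_center + np.array(prov.crop_offset.start)
        mm = iso_voxel * np.array(prov.iso_spacing)
        src_voxel = mm / np.array(prov.original_spacing)
        src_center = np.array(prov.original_shape) / 2
        assert np.all(np.abs(src_voxel - src_center) <= 1.0)


class TestDeriveCrop:
    def _coarse_from_truth(self, phantom, cfg):
        from pericfat.grid import crop_pad_centered, resample

        r = resample(phantom.pericardium_truth, (cfg.iso_spacing_mm,) * 3, "nearest")
        return r

    def test_crop_center_matches_bbox_center_for_interior_heart(self, small_phantom):
        coarse = self._coarse_from_truth(small_phantom, CFG)
        region, cropped = locnet.derive_crop(coarse, small_phantom.image, CFG)
        lo, hi = bounding_box(small_phantom.pericardium_truth)
        m = CFG.safety_margin_voxels
        expected = tuple(((l - m) + (h + m)) // 2 for l, h in zip(lo, hi))
        assert all(abs(a - b) <= 1 for a, b in zip(region.center_voxel, expected))
        assert cropped.shape == tuple(CFG.crop_shape)

    def test_margin_expansion_matches_per_axis_minmax(self):
        rng = np.random.default_rng(0)
        m = (rng.random((40, 40, 40)) < 0.01).astype(np.uint8)
        mask = MaskGrid(m, (2.0, 2.0, 2.0))
        lo, hi = bounding_box(mask)
        marg = CFG.safety_margin_voxels
        exp_lo = tuple(l - marg for l in lo)
        exp_hi = tuple(h + marg for h in hi)
        # brute-force oracle over all foreground voxels
        pts = np.argwhere(m)
        for ax in range(3):
            assert exp_lo[ax] == pts[:, ax].min() - marg
            assert exp_hi[ax] == pts[:, ax].max() + marg

    def test_edge_heart_padded_with_air(self):
        spec = dict(
            SMALL_SPEC,
            heart_radii_mm=(16.0, 14.0, 12.0),
            fat_thickness_mm=5.0,
            heart_center_frac=(0.3, 0.5, 0.3),
            center_jitter_frac=0.0,
            radii_jitter_frac=0.0,
        )
        p = generate_phantom(PhantomSpec(seed=5, **spec))
        coarse = self._coarse_from_truth(p, CFG)
        region, cropped = locnet.derive_crop(coarse, p.image, CFG)
        assert cropped.shape == tuple(CFG.crop_shape)
        assert (cropped.data == -1000.0).any()  # padded region present
        assert any(s < 0 for s in region.offset.start)

    def test_output_shape_independent_of_input_extent(self):
        # coarse 4 mm mask grids covering the same physical extent as the
        # 2 mm source volumes; crop shape must come out exact regardless
        for shape in [(30, 30, 30), (64, 64, 40)]:
            coarse_shape = tuple(s // 2 for s in shape)
            m = np.zeros(coarse_shape, dtype=np.uint8)
            ctr = tuple(s // 2 for s in coarse_shape)
            m[ctr[0] - 2 : ctr[0] + 2, ctr[1] - 2 : ctr[1] + 2, ctr[2] - 2 : ctr[2] + 2] = 1
            v = VolumeGrid(np.zeros(shape), (2.0, 2.0, 2.0))
            region, cropped = locnet.derive_crop(
                MaskGrid(m, (4.0, 4.0, 4.0)), v, CFG
            )
            assert cropped.shape == tuple(CFG.crop_shape)

    def test_empty_mask_rejected(self, small_phantom):
        empty = MaskGrid(np.zeros((32, 32, 32), dtype=np.uint8), (4.0, 4.0, 4.0))
        with pytest.raises(EmptyMaskError):
            locnet.derive_crop(empty, small_phantom.image, CFG)


class TestTrainPredict:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        # overfit a handful of phantoms with a small config: capacity and
        # end-to-end plumbing check in one training run
        phantoms = [
            generate_phantom(PhantomSpec(seed=s, **SMALL_SPEC)) for s in range(1, 7)
        ]
        cfg = locnet.LocConfig.scaled_down(epochs=40)
        model = locnet.train_loc(phantoms, cfg)
        return phantoms, cfg, model

    def test_training_loss_decreases(self, tiny_model):
        _, _, model = tiny_model
        assert model.log.train_loss[-1] < model.log.train_loss[0]

    def test_lr_schedule_recorded(self, tiny_model):
        _, cfg, model = tiny_model
        assert model.log.lr[0] == cfg.lr0

    def test_prediction_recovers_heart_location(self, tiny_model):
        phantoms, cfg, model = tiny_model
        p = phantoms[0]
        coarse = locnet.predict_loc(p.image, model)
        assert set(np.unique(coarse.data)) <= {0, 1}
        from pericfat.grid import bbox_center, resample

        truth_iso = resample(p.pericardium_truth, coarse.spacing_mm, "nearest")
        c_pred = bbox_center(bounding_box(coarse))
        c_true = bbox_center(bounding_box(truth_iso))
        assert all(abs(a - b) <= 5 for a, b in zip(c_pred, c_true))

    def test_all_air_input_fails_localization(self, tiny_model):
        _, cfg, model = tiny_model
        air = VolumeGrid(np.full((48, 48, 48), -1000.0), (2.0, 2.0, 2.0))
        with pytest.raises(locnet.LocalizationFailure):
            locnet.predict_loc(air, model)

    def test_too_few_phantoms_rejected(self):
        with pytest.raises(ValueError):
            locnet.train_loc([], locnet.LocConfig.scaled_down())
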