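"""Stage 2 of the cascade: pericardial-sac segmentation on the cropped heart.

The segmentation network works at higher resolution than localization
(full-scale default: 2.0 x 2.0 x 2.5 mm, 128 x 128 x 80 voxels).  Unlike
stage 1 it redraws its 70/30 train/tune split every 100 epochs, a
rotation-style use of the whole pool that avoids committing a third of
the data purely to tuning.  Predicted masks are mapped back to the
original image geometry (nearest-neighbour upsampling, inverse crop
placement) before evaluation or EAT rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .grid import MaskGrid, VolumeGrid, crop_pad_centered, paste_back, resample
from .locnet import CropRegion, normalize_hu


class ProvenanceError(RuntimeError):
    """Mask restoration requested without a usable preprocessing record."""


@dataclass(frozen=True)
class SegConfig:
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    input_shape: tuple[int, int, int] = (128, 128, 80)
    levels: int = 4
    base_filters: int = 32
    dropout: float = 0.5
    bottleneck_feature_reduction: bool = True
    lr0: float = 1e-4
    lr_decay_factor: float = 0.3
    lr_decay_every: int = 100
    batch_size: int = 4
    epochs: int = 1200
    resplit_every: int = 100
    tune_frac: float = 0.3
    aug_translate_voxels: int = 20
    aug_rotate_deg: float = 35.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.input_shape) or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("shapes and spacings must be positive")
        if not 0.0 < self.lr_decay_factor <= 1.0:
            raise ValueError("lr decay factor must be in (0,1]")

    @classmethod
    def scaled_down(cls, seed: int = 0, epochs: int = 64) -> "SegConfig":
        """Desk-scale profile matching LocConfig.scaled_down crops (2 mm)."""
        return cls(
            spacing_mm=(2.0, 2.0, 2.0),
            input_shape=(48, 48, 32),
            levels=3,
            base_filters=8,
            lr0=1e-3,
            epochs=epochs,
            resplit_every=25,
            aug_translate_voxels=4,
            aug_rotate_deg=10.0,
            seed=seed,
        )


@dataclass
class SegProvenance:
    crop_spacing: tuple[float, float, float]
    crop_shape: tuple[int, int, int]
    crop_origin: tuple[float, float, float]
    net_spacing: tuple[float, float, float]
    resampled_shape: tuple[int, int, int]
    net_crop_offset: object  # CropOffset within the resampled grid


@dataclass
class SegModel:
    config: SegConfig
    net: nn.UNet3d
    log: nn.TrainLog | None = None


def preprocess_seg(cropped: VolumeGrid, cfg: SegConfig) -> tuple[VolumeGrid, SegProvenance]:
    """Resample the stage-1 crop to the network spacing and center-pad."""
    r = resample(cropped, cfg.spacing_mm, mode="linear")
    center = tuple(s // 2 for s in r.shape)
    block, offset = crop_pad_centered(r, center, cfg.input_shape)
    out = VolumeGrid(normalize_hu(block.data), cfg.spacing_mm, block.origin_mm)
    prov = SegProvenance(
        crop_spacing=cropped.spacing_mm,
        crop_shape=cropped.shape,
        crop_origin=cropped.origin_mm,
        net_spacing=cfg.spacing_mm,
        resampled_shape=r.shape,
        net_crop_offset=offset,
    )
    return out, prov


def _truth_on_network_grid(truth_crop: MaskGrid, cfg: SegConfig) -> np.ndarray:
    r = resample(truth_crop, cfg.spacing_mm, mode="nearest")
    center = tuple(s // 2 for s in r.shape)
    block, _ = crop_pad_centered(r, center, cfg.input_shape)
    return block.data.astype(np.float32)


def train_seg(crops, truth_crops, cfg: SegConfig) -> SegModel:
    """Train the segmentation U-Net on (image crop, truth crop) pairs."""
    if len(crops) < 4:
        raise ValueError("need at least 4 crops to train")
    images, masks = [], []
    for c, t in zip(crops, truth_crops):
        pre, _ = preprocess_seg(c, cfg)
        images.append(pre.data)
        masks.append(_truth_on_network_grid(t, cfg))
    net = nn.UNet3d(
        levels=cfg.levels,
        base_filters=cfg.base_filters,
        dropout=cfg.dropout,
        bottleneck_feature_reduction=cfg.bottleneck_feature_reduction,
        seed=cfg.seed,
    )
    log = nn.train_unet(
        net,
        images,
        masks,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr0=cfg.lr0,
        lr_decay_factor=cfg.lr_decay_factor,
        lr_decay_every=cfg.lr_decay_every,
        resplit_every=cfg.resplit_every,
        tune_frac=cfg.tune_frac,
        translate_voxels=cfg.aug_translate_voxels,
        rotate_deg=cfg.aug_rotate_deg,
        seed=cfg.seed,
    )
    return SegModel(config=cfg, net=net, log=log)


def predict_seg(preprocessed: VolumeGrid, model: SegModel) -> MaskGrid:
    """Binary pericardium prediction on the network grid (threshold 0.5)."""
    prob = model.net.forward(preprocessed.data[None, None], train=False)[0, 0]
    return MaskGrid(
        (prob > 0.5).astype(np.uint8), preprocessed.spacing_mm, preprocessed.origin_mm
    )


def restore_mask(
    mask: MaskGrid,
    prov: SegProvenance,
    region: CropRegion,
    original: VolumeGrid,
) -> MaskGrid:
    """Map a network-grid mask back onto the original image geometry.

    Inverts the preprocessing chain: undo the center pad on the resampled
    crop, resample (nearest) to the crop's native spacing, then paste the
    crop back at its recorded offset in the original volume.
    """
    if prov is None or region is None:
        raise ProvenanceError("missing provenance for mask restoration")
    on_resampled = paste_back(mask.data, prov.net_crop_offset)
    rg = MaskGrid(on_resampled, prov.net_spacing, (0.0, 0.0, 0.0))
    native = resample(rg, prov.crop_spacing, mode="nearest")
    if native.shape != tuple(prov.crop_shape):
        native, _ = crop_pad_centered(
            native, tuple(s // 2 for s in native.shape), prov.crop_shape
        )
    full = paste_back(native.data, region.offset)
    return MaskGrid(full, original.spacing_mm, original.origin_mm)
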