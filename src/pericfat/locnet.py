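"""Stage 1 of the cascade: coarse heart localization.

The localization network sees the whole chest at low, isotropic resolution
(full-scale default: 3 mm, 112^3 voxels) and predicts a coarse heart mask.
The mask is mapped back to the original voxel spacing; the center of its
bounding box, expanded by a safety margin on every face, defines a
fixed-size high-resolution crop (384 x 384 x 80 voxels at full scale)
that is handed to the segmentation stage.

A ``scaled_down`` profile (32^3 at 4 mm on 64^3 phantom grids, small
filter counts, tens of epochs) makes the full recipe trainable on a
single CPU in minutes; the full-scale numbers remain the documented
defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .grid import (
    CropOffset,
    EmptyMaskError,
    MaskGrid,
    VolumeGrid,
    bbox_center,
    bounding_box,
    crop_pad_centered,
    paste_back,
    resample,
)

HU_CLIP = (-1000.0, 1000.0)


class LocalizationFailure(RuntimeError):
    """The localization network predicted no heart voxels."""


@dataclass(frozen=True)
class LocConfig:
    iso_spacing_mm: float = 3.0
    input_shape: tuple[int, int, int] = (112, 112, 112)
    crop_shape: tuple[int, int, int] = (384, 384, 80)
    safety_margin_voxels: int = 11
    levels: int = 4
    base_filters: int = 32
    dropout: float = 0.5
    bottleneck_feature_reduction: bool = True
    lr0: float = 1e-4
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 100
    batch_size: int = 3
    epochs: int = 1200
    tune_frac: float = 0.3
    aug_translate_voxels: int = 10
    aug_rotate_deg: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.input_shape + self.crop_shape):
            raise ValueError("shapes must be positive")
        if not 0.0 < self.lr_decay_factor <= 1.0:
            raise ValueError("lr decay factor must be in (0,1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")

    @classmethod
    def scaled_down(cls, seed: int = 0, epochs: int = 20) -> "LocConfig":
        """Desk-scale profile for 64^3 phantoms at 2 mm spacing."""
        return cls(
            iso_spacing_mm=4.0,
            input_shape=(32, 32, 32),
            crop_shape=(48, 48, 32),
            safety_margin_voxels=3,
            levels=3,
            base_filters=8,
            lr0=1e-3,
            epochs=epochs,
            aug_translate_voxels=3,
            aug_rotate_deg=4.0,
            seed=seed,
        )


@dataclass(frozen=True)
class CropRegion:
    """A fixed-size crop in original-resolution voxel coordinates."""

    center_voxel: tuple[int, int, int]
    shape: tuple[int, int, int]
    offset: CropOffset


@dataclass
class LocProvenance:
    """Geometry bookkeeping to map network-grid voxels back to the source."""

    original_spacing: tuple[float, float, float]
    original_shape: tuple[int, int, int]
    original_origin: tuple[float, float, float]
    iso_spacing: tuple[float, float, float]
    iso_shape: tuple[int, int, int]
    crop_offset: CropOffset


@dataclass
class LocModel:
    config: LocConfig
    net: nn.UNet3d
    log: nn.TrainLog | None = None


def normalize_hu(data: np.ndarray) -> np.ndarray:
    """Clip to [-1000, 1000] HU and scale linearly to [0, 1]."""
    lo, hi = HU_CLIP
    return ((np.clip(data, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def preprocess_loc(v: VolumeGrid, cfg: LocConfig) -> tuple[VolumeGrid, LocProvenance]:
    """Resample to isotropic spacing, center-crop/pad, normalize intensity."""
    iso = (cfg.iso_spacing_mm,) * 3
    r = resample(v, iso, mode="linear")
    center = tuple(s // 2 for s in r.shape)
    cropped, offset = crop_pad_centered(r, center, cfg.input_shape)
    out = VolumeGrid(normalize_hu(cropped.data), iso, cropped.origin_mm)
    prov = LocProvenance(
        original_spacing=v.spacing_mm,
        original_shape=v.shape,
        original_origin=v.origin_mm,
        iso_spacing=iso,
        iso_shape=r.shape,
        crop_offset=offset,
    )
    return out, prov


def _mask_on_network_grid(m: MaskGrid, cfg: LocConfig) -> np.ndarray:
    iso = (cfg.iso_spacing_mm,) * 3
    r = resample(m, iso, mode="nearest")
    center = tuple(s // 2 for s in r.shape)
    cropped, _ = crop_pad_centered(r, center, cfg.input_shape)
    return cropped.data.astype(np.float32)


def train_loc(phantoms, cfg: LocConfig) -> LocModel:
    """Train the localization U-Net on phantom images vs pericardium truth."""
    if len(phantoms) < 2:
        raise ValueError("need at least 2 phantoms to train")
    images, masks = [], []
    for p in phantoms:
        pre, _ = preprocess_loc(p.image, cfg)
        images.append(pre.data)
        masks.append(_mask_on_network_grid(p.pericardium_truth, cfg))
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
        resplit_every=None,  # single fixed 70/30 split
        tune_frac=cfg.tune_frac,
        translate_voxels=cfg.aug_translate_voxels,
        rotate_deg=cfg.aug_rotate_deg,
        seed=cfg.seed,
    )
    return LocModel(config=cfg, net=net, log=log)


def predict_loc(v: VolumeGrid, model: LocModel, cfg: LocConfig | None = None) -> MaskGrid:
    """Coarse heart mask on the full isotropic grid of the input volume.

    The probability map is thresholded at 0.5 and only the largest
    connected component is kept.
    """
    cfg = cfg or model.config
    pre, prov = preprocess_loc(v, cfg)
    prob = model.net.forward(pre.data[None, None], train=False)[0, 0]
    binary = prob > 0.5
    if not binary.any():
        raise LocalizationFailure("no voxel above probability 0.5")
    labels, n = ndimage.label(binary)
    if n > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    full = paste_back(binary.astype(np.uint8), prov.crop_offset)
    return MaskGrid(full, prov.iso_spacing, prov.original_origin)


def derive_crop(
    coarse_mask: MaskGrid, original: VolumeGrid, cfg: LocConfig
) -> tuple[CropRegion, VolumeGrid]:
    """Fixed-size high-resolution crop around the expanded coarse bbox.

    The coarse mask is resampled (nearest) to the original spacing, its
    bounding box expanded by ``safety_margin_voxels`` on every face, and a
    ``crop_shape`` block is cut centered on the expanded-box center,
    padding with air where it leaves the volume.
    """
    if coarse_mask.count == 0:
        raise EmptyMaskError("cannot derive a crop from an empty mask")
    at_native = resample(coarse_mask, original.spacing_mm, mode="nearest")
    # align shape to the original grid (rounding in resample can differ by 1)
    if at_native.shape != original.shape:
        at_native, _ = crop_pad_centered(
            at_native, tuple(s // 2 for s in at_native.shape), original.shape
        )
    lo, hi = bounding_box(at_native)
    m = cfg.safety_margin_voxels
    lo = tuple(l - m for l in lo)
    hi = tuple(h + m for h in hi)
    extent = tuple(h - l + 1 for l, h in zip(lo, hi))
    if any(e > s for e, s in zip(extent, cfg.crop_shape)):
        warnings.warn(
            f"expanded heart bbox {extent} exceeds crop shape {cfg.crop_shape}; "
            "the crop may truncate the heart",
            stacklevel=2,
        )
    center = bbox_center((lo, hi))
    cropped, offset = crop_pad_centered(original, center, cfg.crop_shape)
    region = CropRegion(center_voxel=center, shape=tuple(cfg.crop_shape), offset=offset)
    return region, cropped


def crop_from_truth(
    truth: MaskGrid, original: VolumeGrid, cfg: LocConfig
) -> tuple[CropRegion, VolumeGrid]:
    """Crop derived from a ground-truth mask (stage-2 testing without stage 1)."""
    lo, hi = bounding_box(truth)
    m = cfg.safety_margin_voxels
    center = bbox_center((tuple(l - m for l in lo), tuple(h + m for h in hi)))
    cropped, offset = crop_pad_centered(original, center, cfg.crop_shape)
    return CropRegion(center, tuple(cfg.crop_shape), offset), cropped
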