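"""End-to-end training and evaluation of the two-stage segmentation cascade.

Ties together phantom generation, localization training, crop derivation,
segmentation training and mask restoration, mirroring how the full system
is assembled from its stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evalm, locnet, segnet
from .grid import MaskGrid, crop_pad_centered


@dataclass
class Cascade:
    loc: locnet.LocModel
    seg: segnet.SegModel


def train_cascade(
    phantoms,
    loc_cfg: locnet.LocConfig,
    seg_cfg: segnet.SegConfig,
    crops_from_truth: bool = False,
) -> Cascade:
    """Train stage 1, derive stage-2 crops with it, then train stage 2.

    Stage-2 training inputs are the crops the trained localization model
    produces on the training phantoms (set ``crops_from_truth`` to bypass
    stage 1 with ground-truth-derived crops, e.g. in unit tests).
    """
    loc_model = locnet.train_loc(phantoms, loc_cfg)
    crops, truth_crops = [], []
    for p in phantoms:
        if crops_from_truth:
            region, cropped = locnet.crop_from_truth(
                p.pericardium_truth, p.image, loc_cfg
            )
        else:
            coarse = locnet.predict_loc(p.image, loc_model)
            region, cropped = locnet.derive_crop(coarse, p.image, loc_cfg)
        crops.append(cropped)
        truth, _ = crop_pad_centered(
            p.pericardium_truth, region.center_voxel, loc_cfg.crop_shape
        )
        truth_crops.append(truth)
    seg_model = segnet.train_seg(crops, truth_crops, seg_cfg)
    return Cascade(loc=loc_model, seg=seg_model)


def predict_pericardium(image, cascade: Cascade) -> MaskGrid:
    """Run the full cascade on one volume; restored mask at original geometry."""
    coarse = locnet.predict_loc(image, cascade.loc)
    region, cropped = locnet.derive_crop(coarse, image, cascade.loc.config)
    pre, prov = segnet.preprocess_seg(cropped, cascade.seg.config)
    pred = segnet.predict_seg(pre, cascade.seg)
    return segnet.restore_mask(pred, prov, region, image)


def evaluate_cascade(phantoms, cascade: Cascade) -> evalm.SegEval:
    """Dice / surface distance of restored predictions vs truth pericardium."""
    preds = [predict_pericardium(p.image, cascade) for p in phantoms]
    truths = [p.pericardium_truth for p in phantoms]
    return evalm.evaluate_cases(preds, truths)
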