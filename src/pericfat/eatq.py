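"""Epicardial adipose tissue (EAT) rendering and scalar measures.

EAT is defined as all voxels inside the pericardial sac whose attenuation
falls in a fixed fat window of -190 to -30 HU (bounds inclusive).  The
scalar outputs used downstream are the absolute EAT volume (cm^3), the
body-surface-area-indexed volume (cm^3/m^2) and the mean density (HU).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .grid import GridError, MaskGrid, VolumeGrid


class EmptyEATError(ValueError):
    """Density requested for an empty EAT mask (volume 0, density undefined)."""


@dataclass(frozen=True)
class EATWindow:
    """Inclusive HU window used to render fat inside the pericardial sac."""

    lo_hu: float = -190.0
    hi_hu: float = -30.0

    def __post_init__(self) -> None:
        if not self.lo_hu < self.hi_hu:
            raise ValueError(f"window lower bound must be below upper, got {self}")


DEFAULT_WINDOW = EATWindow()


@dataclass(frozen=True)
class BodyHabitus:
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError(f"height and weight must be positive, got {self}")


@dataclass(frozen=True)
class EATMeasures:
    """Scalar EAT quantities for one scan.

    ``density_hu`` is None (undefined, not NaN) when no EAT voxel exists.
    """

    volume_cm3: float
    bsa_m2: float
    volume_indexed_cm3_per_m2: float
    density_hu: float | None
    voxel_count: int
    window: EATWindow = DEFAULT_WINDOW
    bsa_formula: str = "dubois"

    @property
    def density_defined(self) -> bool:
        return self.density_hu is not None


def body_surface_area(
    height_cm: float, weight_kg: float, formula: Literal["dubois", "mosteller"] = "dubois"
) -> float:
    """Body surface area in m^2.

    Du Bois (default): 0.007184 * h^0.725 * w^0.425;
    Mosteller: sqrt(h * w / 3600).
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    raise ValueError(f"unknown BSA formula {formula!r}")


def render_eat(
    image: VolumeGrid, heart_mask: MaskGrid, window: EATWindow = DEFAULT_WINDOW
) -> MaskGrid:
    """Fat voxels inside the pericardial mask: mask AND lo <= HU <= hi."""
    if not image.same_geometry(heart_mask):
        raise GridError("image and pericardial mask geometries differ")
    inside = (image.data >= window.lo_hu) & (image.data <= window.hi_hu)
    return MaskGrid(
        (inside & (heart_mask.data > 0)).astype(np.uint8),
        image.spacing_mm,
        image.origin_mm,
    )


def eat_volume(eat_mask: MaskGrid) -> float:
    """Volume in cm^3: voxel count times voxel volume (mm^3 -> cm^3)."""
    return eat_mask.count * eat_mask.voxel_volume_mm3 / 1000.0


def eat_density(image: VolumeGrid, eat_mask: MaskGrid) -> float:
    """Mean attenuation (HU) over the EAT voxels; undefined if none."""
    if not image.same_geometry(eat_mask):
        raise GridError("image and EAT mask geometries differ")
    if eat_mask.count == 0:
        raise EmptyEATError("density undefined for an empty EAT mask")
    return float(image.data[eat_mask.data > 0].mean())


def quantify(
    image: VolumeGrid,
    heart_mask: MaskGrid,
    body: BodyHabitus,
    window: EATWindow = DEFAULT_WINDOW,
    bsa_formula: Literal["dubois", "mosteller"] = "dubois",
) -> EATMeasures:
    """Render EAT inside the pericardial mask and compute all measures."""
    eat = render_eat(image, heart_mask, window)
    vol = eat_volume(eat)
    bsa = body_surface_area(body.height_cm, body.weight_kg, bsa_formula)
    density = eat_density(image, eat) if eat.count > 0 else None
    return EATMeasures(
        volume_cm3=vol,
        bsa_m2=bsa,
        volume_indexed_cm3_per_m2=vol / bsa,
        density_hu=density,
        voxel_count=eat.count,
        window=window,
        bsa_formula=bsa_formula,
    )


def run_pipeline(image, loc_model, seg_model, body, window=DEFAULT_WINDOW, bsa_formula="dubois"):
    """Full cascade: localize the heart, segment the pericardium, quantify.

    Returns ``(measures, restored_pericardium_mask, eat_mask)``.  Stage
    failures propagate with the failing stage named in the message.
    """
    from . import locnet, segnet  # deferred: avoids import cycle

    try:
        coarse = locnet.predict_loc(image, loc_model)
    except Exception as e:  # noqa: BLE001 - annotate stage then re-raise
        raise RuntimeError(f"localization stage failed: {e}") from e
    try:
        region, cropped = locnet.derive_crop(coarse, image, loc_model.config)
        pre, prov = segnet.preprocess_seg(cropped, seg_model.config)
        pred = segnet.predict_seg(pre, seg_model)
        peri = segnet.restore_mask(pred, prov, region, image)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"segmentation stage failed: {e}") from e
    try:
        measures = quantify(image, peri, body, window, bsa_formula)
        eat = render_eat(image, peri, window)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"quantification stage failed: {e}") from e
    return measures, peri, eat
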