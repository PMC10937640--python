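"""Procedural chest-CT phantoms with known pericardium and EAT ground truth.

Each phantom is a torso-like HU volume: background air, an elliptic-cylinder
torso of soft tissue wrapped in a subcutaneous fat ring, two lung fields,
and a heart ellipsoid enclosed by a pericardial sac whose inner shell
contains fat in the -190..-30 HU window.  The truth masks are frozen before
noise is added; after noise, fat-voxel HUs are re-clipped to the window so
the recorded EAT truth stays consistent with the image.

The generator is the training and evaluation substrate for the whole
segmentation cascade: it trades anatomical realism for exact, analytically
checkable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import eatq
from .grid import MaskGrid, VolumeGrid

EAT_LO, EAT_HI = -190.0, -30.0

#: per-class HU mean/SD: fat sits mid-window; myocardium/blood and
#: mediastinal soft tissue share ~+40 HU so the sac boundary is defined by
#: the fat shell, as on real non-contrast CT.
DEFAULT_HU = {
    "air": (-1000.0, 4.0),
    "lung": (-800.0, 30.0),
    "soft": (40.0, 12.0),
    "heart": (40.0, 10.0),
    "fat": (-100.0, 20.0),
    "subcut_fat": (-100.0, 15.0),
}


class PhantomSpecError(ValueError):
    """Spec violates an invariant (e.g. heart does not fit in the grid)."""


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    heart_center_frac: tuple[float, float, float] = (0.5, 0.5, 0.5)
    heart_radii_mm: tuple[float, float, float] = (30.0, 26.0, 18.0)
    fat_thickness_mm: float = 6.0
    fat_fraction: float = 0.9
    hu_params: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    noise_sd_hu: float = 10.0
    center_jitter_frac: float = 0.04
    radii_jitter_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise PhantomSpecError(f"grid_shape must be >=16 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomSpecError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise PhantomSpecError(f"fat_fraction must be in [0,1], got {self.fat_fraction}")
        fat_mean = self.hu_params["fat"][0]
        if not EAT_LO < fat_mean < EAT_HI:
            raise PhantomSpecError(
                f"fat HU mean must lie inside ({EAT_LO}, {EAT_HI}), got {fat_mean}"
            )


@dataclass
class Phantom:
    image: VolumeGrid
    pericardium_truth: MaskGrid
    eat_truth: MaskGrid
    height_cm: float
    weight_kg: float

    @property
    def body(self) -> eatq.BodyHabitus:
        return eatq.BodyHabitus(self.height_cm, self.weight_kg)


def _ellipsoid(coords, center_mm, radii_mm):
    q = sum(((c - m) / r) ** 2 for c, m, r in zip(coords, center_mm, radii_mm))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build one phantom; bit-identical for identical spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    sp = np.asarray(spec.spacing_mm, dtype=float)
    extent = np.asarray(shape) * sp
    # voxel-center physical coordinates
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)], indexing="ij"
    )

    # jittered heart geometry (seeded, part of the phantom's identity)
    center = np.asarray(spec.heart_center_frac) * extent
    center = center + rng.uniform(-1, 1, 3) * spec.center_jitter_frac * extent
    radii = np.asarray(spec.heart_radii_mm) * (
        1.0 + rng.uniform(-1, 1, 3) * spec.radii_jitter_frac
    )
    sac_radii = radii + spec.fat_thickness_mm
    if np.any(center - sac_radii < 0) or np.any(center + sac_radii > extent):
        raise PhantomSpecError(
            f"pericardial sac (center {center} mm, radii {sac_radii} mm) "
            f"does not fit inside the {extent} mm grid"
        )

    hu = spec.hu_params
    img = np.full(shape, hu["air"][0], dtype=np.float64)

    # torso: elliptic cylinder along z with a subcutaneous fat ring
    torso_c = extent / 2.0
    torso_r = np.array([0.47 * extent[0], 0.44 * extent[1]])
    rho = ((coords[0] - torso_c[0]) / torso_r[0]) ** 2 + (
        (coords[1] - torso_c[1]) / torso_r[1]
    ) ** 2
    torso = rho <= 1.0
    img[torso] = hu["soft"][0]
    img[torso & (rho > 0.88**2)] = hu["subcut_fat"][0]

    # lungs: lateral ellipsoids clipped to the inner torso
    for side in (-1.0, +1.0):
        lung_c = np.array([torso_c[0] + side * 0.27 * extent[0], torso_c[1], torso_c[2]])
        lung_r = np.array([0.16 * extent[0], 0.24 * extent[1], 0.42 * extent[2]])
        lung = _ellipsoid(coords, lung_c, lung_r) & (rho <= 0.85**2)
        img[lung] = hu["lung"][0]

    # pericardial sac: heart core plus an inner fat shell
    sac = _ellipsoid(coords, center, sac_radii)
    core = _ellipsoid(coords, center, radii)
    shell = sac & ~core
    img[sac] = hu["heart"][0]

    fat_sel = shell & (rng.random(shape) < spec.fat_fraction)
    n_fat = int(fat_sel.sum())
    fat_hu = np.clip(
        rng.normal(hu["fat"][0], hu["fat"][1], n_fat), EAT_LO, EAT_HI
    )
    img[fat_sel] = fat_hu

    pericardium = MaskGrid(sac.astype(np.uint8), tuple(sp), (0.0, 0.0, 0.0))
    eat = MaskGrid(fat_sel.astype(np.uint8), tuple(sp), (0.0, 0.0, 0.0))

    # truth frozen above; now add acquisition noise and re-clip fat voxels
    if spec.noise_sd_hu > 0:
        img = img + rng.normal(0.0, spec.noise_sd_hu, shape)
    img[fat_sel] = np.clip(img[fat_sel], EAT_LO, EAT_HI)

    height = float(np.clip(rng.normal(170.0, 10.0), 120.0, 220.0))
    weight = float(np.clip(rng.normal(80.0, 15.0), 35.0, 200.0))
    return Phantom(
        image=VolumeGrid(img, tuple(sp), (0.0, 0.0, 0.0)),
        pericardium_truth=pericardium,
        eat_truth=eat,
        height_cm=height,
        weight_kg=weight,
    )


def truth_measures(p: Phantom, bsa_formula: str = "dubois") -> eatq.EATMeasures:
    """EAT measures from the ground-truth fat mask (pipeline oracle).

    Uses the same volume/density/BSA formulas as the automated pipeline,
    applied to ``eat_truth`` directly.
    """
    vol = eatq.eat_volume(p.eat_truth)
    bsa = eatq.body_surface_area(p.height_cm, p.weight_kg, bsa_formula)
    density = (
        eatq.eat_density(p.image, p.eat_truth) if p.eat_truth.count > 0 else None
    )
    return eatq.EATMeasures(
        volume_cm3=vol,
        bsa_m2=bsa,
        volume_indexed_cm3_per_m2=vol / bsa,
        density_hu=density,
        voxel_count=p.eat_truth.count,
        bsa_formula=bsa_formula,
    )


def phantom_pool(n: int, base_seed: int = 1, **spec_kwargs) -> list[Phantom]:
    """Generate ``n`` phantoms with seeds base_seed..base_seed+n-1."""
    return [
        generate_phantom(PhantomSpec(seed=base_seed + i, **spec_kwargs)) for i in range(n)
    ]


def save_phantom(p: Phantom, outdir) -> None:
    from pathlib import Path

    from .grid import write_volume

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(p.image, out / "image.nii.gz")
    write_volume(p.pericardium_truth, out / "pericardium.nii.gz")
    write_volume(p.eat_truth, out / "eat.nii.gz")
    (out / "body.json").write_text(
        json.dumps({"height_cm": p.height_cm, "weight_kg": p.weight_kg}, indent=2)
    )
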