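"""Volume containers, NIfTI I/O and the geometric primitives of the pipeline.

All imaging stages operate on :class:`VolumeGrid` (a 3D scalar image in
Hounsfield units with anisotropic voxel spacing) and :class:`MaskGrid`
(a binary label sharing a grid geometry).  Conventions used throughout:

* voxel indexing is 0-based, axis order (x, y, z) with z the cranio-caudal
  ("axial") axis;
* bounding boxes are inclusive at both ends;
* box midpoints with .5 fractions round down (``floor``), so every derived
  center is a deterministic integer voxel;
* padding of CT images uses -1000 HU (air), masks pad with 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

AIR_HU = -1000.0


class GridError(ValueError):
    """Malformed grid or geometry mismatch between grids."""


class EmptyMaskError(ValueError):
    """An operation that needs foreground voxels received an empty mask."""


def _as_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    s = tuple(float(x) for x in spacing)
    if len(s) != 3 or any(x <= 0 for x in s):
        raise GridError(f"spacing must be three positive floats, got {spacing!r}")
    return s  # type: ignore[return-value]


@dataclass
class VolumeGrid:
    """A 3D scalar image in HU on a regular anisotropic grid."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GridError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise GridError("volume contains non-finite values")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(x) for x in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_geometry(self, other: "VolumeGrid | MaskGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )


@dataclass
class MaskGrid:
    """A binary 3D label on a :class:`VolumeGrid` geometry."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise GridError(f"expected a 3D array, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise GridError(f"mask values must be in {{0,1}}, got {uniq[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(x) for x in self.origin_mm)

    shape = VolumeGrid.shape
    voxel_volume_mm3 = VolumeGrid.voxel_volume_mm3
    same_geometry = VolumeGrid.same_geometry

    @property
    def count(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> VolumeGrid:
    """Read a 3D NIfTI volume, reoriented to RAS, spacing from the affine."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GridError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise GridError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VolumeGrid(np.asarray(data, dtype=np.float64), tuple(zooms), origin)


def write_volume(v: VolumeGrid | MaskGrid, path) -> None:
    """Write a grid as NIfTI with a diagonal RAS affine (round-trips exactly)."""
    affine = np.diag(list(v.spacing_mm) + [1.0])
    affine[:3, 3] = v.origin_mm
    data = v.data.astype(np.uint8) if isinstance(v, MaskGrid) else v.data
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_mask(path) -> MaskGrid:
    v = read_volume(path)
    return MaskGrid((v.data > 0.5).astype(np.uint8), v.spacing_mm, v.origin_mm)


# ---------------------------------------------------------------------------
# Resampling


def resample(
    v: VolumeGrid | MaskGrid,
    target_spacing_mm: Sequence[float],
    mode: str | None = None,
) -> VolumeGrid | MaskGrid:
    """Resample to a new voxel spacing.

    Images use trilinear interpolation, masks nearest-neighbour; ``mode``
    overrides the default ("linear" or "nearest").  The physical extent is
    preserved to within one voxel; the origin is kept.
    """
    target = _as_spacing(target_spacing_mm)
    if mode is None:
        mode = "nearest" if isinstance(v, MaskGrid) else "linear"
    if mode not in ("linear", "nearest"):
        raise GridError(f"unknown resampling mode {mode!r}")
    factors = [s / t for s, t in zip(v.spacing_mm, target)]
    new_shape = tuple(int(round(n * f)) for n, f in zip(v.shape, factors))
    if any(n == 0 for n in new_shape):
        raise GridError(f"resampling to {target} collapses the grid: {new_shape}")
    if new_shape == v.shape and np.allclose(v.spacing_mm, target):
        out = v.data.copy()
    else:
        # voxel-center mapping: output center (i+.5)*t_mm lands at source
        # index ((i+.5)*t/s - .5), keeping the lattice metrically exact
        order = 0 if mode == "nearest" else 1
        ratio = [t / s for s, t in zip(v.spacing_mm, target)]
        offset = [0.5 * r - 0.5 for r in ratio]
        src = v.data if mode == "nearest" else v.data.astype(np.float64)
        out = ndimage.affine_transform(
            src,
            np.asarray(ratio),
            offset=offset,
            output_shape=new_shape,
            order=order,
            mode="nearest",
        )
    if isinstance(v, MaskGrid):
        return MaskGrid(out.astype(np.uint8), target, v.origin_mm)
    return VolumeGrid(out, target, v.origin_mm)


# ---------------------------------------------------------------------------
# Cropping / padding


@dataclass(frozen=True)
class CropOffset:
    """Voxel offset of a crop in source coordinates (may be negative)."""

    start: tuple[int, int, int]
    source_shape: tuple[int, int, int]


def crop_pad_centered(
    v: VolumeGrid | MaskGrid,
    center_voxel: Sequence[int],
    shape: Sequence[int],
    fill: float | None = None,
) -> tuple[VolumeGrid | MaskGrid, CropOffset]:
    """Extract a ``shape``-sized block centered on ``center_voxel``.

    Regions that fall outside the source are padded (images with air at
    -1000 HU, masks with 0).  Returns the block plus the offset of its
    first voxel in source coordinates so results can be pasted back.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise GridError(f"crop shape must be positive, got {shape}")
    center = tuple(int(c) for c in center_voxel)
    start = tuple(c - s // 2 for c, s in zip(center, shape))
    if fill is None:
        fill = 0 if isinstance(v, MaskGrid) else AIR_HU
    out = np.full(shape, fill, dtype=v.data.dtype if isinstance(v, MaskGrid) else np.float64)
    src_lo = [max(0, st) for st in start]
    src_hi = [min(n, st + s) for n, st, s in zip(v.shape, start, shape)]
    dst_lo = [sl - st for sl, st in zip(src_lo, start)]
    dst_hi = [dl + (sh - sl) for dl, sl, sh in zip(dst_lo, src_lo, src_hi)]
    if all(hi > lo for lo, hi in zip(src_lo, src_hi)):
        out[tuple(slice(l, h) for l, h in zip(dst_lo, dst_hi))] = v.data[
            tuple(slice(l, h) for l, h in zip(src_lo, src_hi))
        ]
    new_origin = tuple(
        o + st * sp for o, st, sp in zip(v.origin_mm, start, v.spacing_mm)
    )
    offset = CropOffset(start=start, source_shape=v.shape)
    if isinstance(v, MaskGrid):
        return MaskGrid(out, v.spacing_mm, new_origin), offset
    return VolumeGrid(out, v.spacing_mm, new_origin), offset


def paste_back(
    block: np.ndarray, offset: CropOffset, into: np.ndarray | None = None, fill: float = 0.0
) -> np.ndarray:
    """Place a cropped block back onto the source grid (inverse of crop)."""
    if into is None:
        into = np.full(offset.source_shape, fill, dtype=block.dtype)
    start, shape = offset.start, block.shape
    src_lo = [max(0, st) for st in start]
    src_hi = [min(n, st + s) for n, st, s in zip(offset.source_shape, start, shape)]
    blk_lo = [sl - st for sl, st in zip(src_lo, start)]
    blk_hi = [bl + (sh - sl) for bl, sl, sh in zip(blk_lo, src_lo, src_hi)]
    if all(hi > lo for lo, hi in zip(src_lo, src_hi)):
        into[tuple(slice(l, h) for l, h in zip(src_lo, src_hi))] = block[
            tuple(slice(l, h) for l, h in zip(blk_lo, blk_hi))
        ]
    return into


# ---------------------------------------------------------------------------
# Bounding boxes


def bounding_box(m: MaskGrid) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Tight inclusive axis-aligned bounding box of the mask foreground."""
    if m.count == 0:
        raise EmptyMaskError("bounding_box of an empty mask")
    idx = np.nonzero(m.data)
    lo = tuple(int(ax.min()) for ax in idx)
    hi = tuple(int(ax.max()) for ax in idx)
    return lo, hi


def bbox_center(box: tuple[tuple[int, int, int], tuple[int, int, int]]) -> tuple[int, int, int]:
    """Midpoint of an inclusive box; .5 fractions round down."""
    lo, hi = box
    return tuple((l + h) // 2 for l, h in zip(lo, hi))
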