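"""Segmentation evaluation: Dice overlap and boundary surface distance.

Surface distance is defined on boundary-voxel centers (mask voxels with at
least one face-neighbour outside the mask): for each boundary voxel of one
mask the Euclidean distance (in mm, anisotropic spacing respected) to the
nearest boundary voxel of the other, pooled symmetrically; the median of
the pooled distances is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import EmptyMaskError, GridError, MaskGrid

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def dice(a: MaskGrid, b: MaskGrid) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 if both masks are empty."""
    if a.shape != b.shape or not np.allclose(a.spacing_mm, b.spacing_mm):
        raise GridError("masks must share geometry for Dice")
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask.astype(bool) & ~ndimage.binary_erosion(
        mask.astype(bool), structure=_FACE_STRUCT, border_value=0
    )


def surface_distance(a: MaskGrid, b: MaskGrid) -> tuple[np.ndarray, float]:
    """Pooled symmetric boundary distances (mm) and their median."""
    if a.shape != b.shape or not np.allclose(a.spacing_mm, b.spacing_mm):
        raise GridError("masks must share geometry for surface distance")
    if a.count == 0 or b.count == 0:
        raise EmptyMaskError("surface distance needs two nonempty masks")
    ba, bb = _boundary(a.data), _boundary(b.data)
    spacing = a.spacing_mm
    # EDT of "not on boundary of X" sampled at boundary of Y gives, for each
    # Y-boundary voxel, the distance to the nearest X-boundary voxel center.
    d_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
    pooled = np.concatenate([d_to_b[ba], d_to_a[bb]])
    return pooled, float(np.median(pooled))


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class SegEval:
    """Per-case segmentation scores plus summary medians and IQRs."""

    table: pd.DataFrame  # columns: case, dice, median_surface_distance_mm

    @property
    def median_dice(self) -> float:
        return float(self.table["dice"].median())

    @property
    def median_surface_distance_mm(self) -> float:
        return float(self.table["median_surface_distance_mm"].median())

    def summary(self) -> dict:
        q = self.table.quantile([0.25, 0.5, 0.75], numeric_only=True)
        return {
            "n": len(self.table),
            "dice_median": float(q.loc[0.5, "dice"]),
            "dice_iqr": float(q.loc[0.75, "dice"] - q.loc[0.25, "dice"]),
            "msd_median_mm": float(q.loc[0.5, "median_surface_distance_mm"]),
            "msd_iqr_mm": float(
                q.loc[0.75, "median_surface_distance_mm"]
                - q.loc[0.25, "median_surface_distance_mm"]
            ),
        }


def evaluate_cases(pred_masks, truth_masks, case_ids=None) -> SegEval:
    """Dice and median surface distance for paired prediction/truth masks."""
    rows = []
    ids = case_ids if case_ids is not None else range(len(pred_masks))
    for cid, p, t in zip(ids, pred_masks, truth_masks):
        d = dice(p, t)
        if p.count > 0 and t.count > 0:
            _, msd = surface_distance(p, t)
        else:
            msd = np.nan
        rows.append({"case": cid, "dice": d, "median_surface_distance_mm": msd})
    return SegEval(pd.DataFrame(rows))
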