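"""Per-case ablation performance metrics.

Dice overlap, signed surface distance with absolute-average-error (AAE)
aggregation, the vascular-fraction heat-sink proxy, and the relative
volume difference |dV|/V_gt.  Surfaces are voxel point sets (mask minus
its 6-connected erosion); signed distances follow the convention that a
predicted-surface point *outside* the ground truth is positive (ground
truth locally enclosed) and one inside is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, UndefinedMetricError
from .grid import VoxelGrid, spheroid_mask

__all__ = [
    "SurfaceDistanceResult",
    "dice",
    "signed_surface_distance",
    "vascular_fraction",
    "case_vascular_fraction",
    "relative_volume_difference",
]


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Sorensen-Dice overlap 2|A^B|/(|A|+|B|); 1 is a perfect match, 0 a
    complete mismatch.  Undefined (raises) when both masks are empty."""
    if mask_a.shape != mask_b.shape:
        raise GeometryError("masks must share a grid")
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise UndefinedMetricError("Dice of two empty masks is undefined")
    return 2.0 * int((a & b).sum()) / denom


@dataclass(frozen=True)
class SurfaceDistanceResult:
    """Signed distances (mm) on the predicted-ablation surface."""

    distances_mm: np.ndarray   # one per predicted-surface voxel
    aae_mm: float              # mean absolute distance (AAE)
    max_abs_mm: float
    mean_signed_mm: float
    positive_is_outside_gt: bool = True


def _surface(mask: np.ndarray) -> np.ndarray:
    struct = ndimage.generate_binary_structure(3, 1)
    return mask & ~ndimage.binary_erosion(mask, structure=struct)


def signed_surface_distance(pred: np.ndarray, gt: np.ndarray,
                            grid: VoxelGrid) -> SurfaceDistanceResult:
    """Signed distance from each predicted-surface point to the nearest
    ground-truth surface point; positive where the predicted surface lies
    outside the ground truth."""
    if pred.shape != grid.shape or gt.shape != grid.shape:
        raise GeometryError("masks must match the grid")
    if not pred.any() or not gt.any():
        raise UndefinedMetricError("surface distance of an empty mask is undefined")
    pred_surf = _surface(pred.astype(bool))
    gt_surf = _surface(gt.astype(bool))
    dist_to_gt_surf = ndimage.distance_transform_edt(~gt_surf, sampling=grid.spacing)
    unsigned = dist_to_gt_surf[pred_surf]
    sign = np.where(gt.astype(bool)[pred_surf], -1.0, 1.0)
    signed = sign * unsigned
    return SurfaceDistanceResult(
        distances_mm=signed,
        aae_mm=float(np.abs(signed).mean()),
        max_abs_mm=float(np.abs(signed).max()),
        mean_signed_mm=float(signed.mean()),
    )


def vascular_fraction(vessel_mask: np.ndarray, plan, power_w: float,
                      duration_s: float, table, grid: VoxelGrid) -> float:
    """Fraction of the manufacturer reference ellipsoid occupied by vessels.

    The ellipsoid dimensions come from the manufacturer table at the
    planned power/duration; it is centered on the active-zone center and
    aligned with the applicator axis.  Assessed *prior* to simulation as
    a proxy for the expected cooling effect.
    """
    from .applicator import manufacturer_lookup

    if vessel_mask.shape != grid.shape:
        raise GeometryError("vessel mask does not match grid")
    length_mm, diameter_mm = manufacturer_lookup(table, power_w, duration_s)
    center = plan.active_zone_center
    u = np.asarray(plan.direction, dtype=float)
    half = np.maximum(np.abs(u) * length_mm / 2.0,
                      np.sqrt(np.maximum(1 - u**2, 0.0)) * diameter_mm / 2.0)
    if not (grid.contains_world(center - half) and grid.contains_world(center + half)):
        raise GeometryError("manufacturer ellipsoid extends outside the grid")
    ell = spheroid_mask(grid, center, u, length_mm, diameter_mm)
    n_ell = int(ell.sum())
    if n_ell == 0:
        raise GeometryError("manufacturer ellipsoid voxelizes to an empty mask")
    return int((ell & vessel_mask.astype(bool)).sum()) / n_ell


def case_vascular_fraction(case, table) -> float:
    """Per-case vascular fraction: maximum over the per-ablation ellipsoids
    (one value is reported per case even with multiple ablations)."""
    fractions = [
        vascular_fraction(case.vessel_mask, plan, power, dur, table, case.grid)
        for plan, (power, dur) in zip(case.plans, case.settings)
    ]
    return max(fractions)


def relative_volume_difference(pred: np.ndarray, gt: np.ndarray) -> float:
    """| |pred| - |gt| | / |gt| by voxel counts (shared grid)."""
    if pred.shape != gt.shape:
        raise GeometryError("masks must share a grid")
    n_gt = int(gt.astype(bool).sum())
    if n_gt == 0:
        raise UndefinedMetricError("relative volume difference with empty ground truth")
    n_pred = int(pred.astype(bool).sum())
    return abs(n_pred - n_gt) / n_gt
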