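"""Arrhenius thermal damage, ablation masks, and mask utilities.

Thermal injury is accumulated as the dimensionless Arrhenius integral

    Omega(t) = integral A * exp(-Ea / (R * T_K(t))) dt,

and tissue is counted as ablated once Omega crosses a threshold
(default 1, the 63.2% protein-denaturation convention).  Sequential
ablations are thermally independent, so masks are computed per ablation
and then united voxelwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .grid import VoxelGrid, check_same_grid

__all__ = [
    "DamageField",
    "DamageParams",
    "arrhenius_update",
    "time_to_threshold",
    "ablation_mask",
    "unite_ablations",
    "ellipsoid_dimensions",
]


@dataclass(frozen=True)
class DamageParams:
    """Arrhenius kinetics for liver coagulation.

    Defaults are literature values for hepatic tissue; they are
    configurable and are echoed into every result manifest because the
    predicted ablation extent is sensitive to them.
    """

    a_freq: float = 7.39e39      # frequency factor, 1/s
    ea: float = 2.577e5          # activation energy, J/mol
    r_gas: float = 8.314462618   # gas constant, J/(mol K)
    threshold: float = 1.0       # Omega defining ablation

    def __post_init__(self) -> None:
        if self.a_freq <= 0 or self.ea <= 0:
            raise ValueError("A and Ea must be positive")

    def rate(self, temp_c) -> np.ndarray:
        """Damage accrual rate k(T) = A*exp(-Ea/(R*T_K)) in 1/s."""
        t_k = np.asarray(temp_c, dtype=float) + 273.15
        if np.any(t_k <= 0):
            raise ValueError("non-physical temperature at or below 0 K")
        return self.a_freq * np.exp(-self.ea / (self.r_gas * t_k))


@dataclass
class DamageField:
    grid: VoxelGrid
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != self.grid.shape:
            raise GeometryError("damage array does not match grid shape")
        if np.any(self.omega < 0):
            raise ValueError("Omega must be nonnegative")

    @classmethod
    def zeros(cls, grid: VoxelGrid) -> "DamageField":
        return cls(grid, np.zeros(grid.shape))


def arrhenius_update(damage: DamageField, temp, dt: float, params: DamageParams) -> DamageField:
    """Accumulate Omega += dt * A * exp(-Ea/(R*T_K)) voxelwise."""
    t_values = temp.values if hasattr(temp, "values") else np.asarray(temp)
    if hasattr(temp, "grid"):
        check_same_grid(damage.grid, temp.grid)
    if t_values.shape != damage.omega.shape:
        raise GeometryError("temperature and damage fields differ in shape")
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    if dt == 0:
        return DamageField(damage.grid, damage.omega.copy())
    return DamageField(damage.grid, damage.omega + dt * params.rate(t_values))


def time_to_threshold(temp_c: float, params: DamageParams) -> float:
    """Closed-form hold time at constant temperature for Omega = threshold."""
    return float(params.threshold / params.rate(temp_c))


def ablation_mask(damage: DamageField, params: DamageParams) -> np.ndarray:
    return damage.omega >= params.threshold


def unite_ablations(masks: list[np.ndarray] | list) -> np.ndarray:
    """Voxelwise OR of per-ablation masks (all on one grid)."""
    if len(masks) == 0:
        raise ValueError("no masks to unite")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise GeometryError(f"masks on different grids: shapes {shapes}")
    out = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        out |= m.astype(bool)
    return out


def ellipsoid_dimensions(mask: np.ndarray, grid: VoxelGrid, axis) -> tuple[float, float]:
    """Length along ``axis`` and max diameter across it through the centroid.

    Extents are voxel-center spans plus one voxel of support, so a
    voxelized ellipsoid of known dimensions is recovered to +-1 voxel.
    """
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise GeometryError("ellipsoid dimensions of an empty mask are undefined")
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    pts = grid.voxel_to_world(idx)
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    s = rel @ u
    h = float(np.mean(grid.spacing))
    length = float(s.max() - s.min()) + h

    # radial extent measured in the slab |s - 0| <= half a voxel around the centroid
    slab = np.abs(s) <= h / 2.0 + 1e-9
    if not slab.any():
        slab = np.abs(s) <= h  # sparse masks: widen the slab
    r2 = np.einsum("ij,ij->i", rel[slab], rel[slab]) - s[slab] ** 2
    diameter = 2.0 * float(np.sqrt(max(r2.max(), 0.0))) + h
    return length, diameter


def smooth_dimensions(
    omega: np.ndarray, grid: VoxelGrid, center, axis, params: DamageParams
) -> tuple[float, float]:
    """Sub-voxel ablation dimensions from the continuous damage field.

    Finds the Omega = threshold crossing of log-Omega sampled along the
    applicator axis (length) and along two perpendicular rays through
    ``center`` (diameter), with linear interpolation between samples.
    Used by source calibration, where voxel-quantized extents would make
    the objective piecewise constant.
    """
    from scipy.ndimage import map_coordinates

    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    # two perpendicular unit vectors
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)

    log_omega = np.log(np.maximum(omega, 1e-300))
    log_thr = np.log(params.threshold)
    step = float(min(grid.spacing)) / 2.0
    max_r = float(max(grid.extent_mm))

    def ray_crossing(direction) -> float:
        n = int(max_r / step)
        ts = np.arange(n) * step
        pts = np.asarray(center)[None, :] + ts[:, None] * direction[None, :]
        vox = grid.world_to_voxel(pts).T
        vals = map_coordinates(log_omega, vox, order=1, mode="constant", cval=-700.0)
        below = np.nonzero(vals < log_thr)[0]
        if below.size == 0:
            return float(ts[-1])
        k = below[0]
        if k == 0:
            return 0.0
        f = (vals[k - 1] - log_thr) / (vals[k - 1] - vals[k])
        return float(ts[k - 1] + f * step)

    length = ray_crossing(u) + ray_crossing(-u)
    diameter = sum(ray_crossing(d) for d in (v, -v, w, -w)) / 2.0
    return length, diameter
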