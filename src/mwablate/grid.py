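"""Regular voxel grid geometry and mask voxelization helpers.

All world coordinates are in millimetres, axes ordered (x, y, z), and
arrays are indexed ``[ix, iy, iz]``.  The grid origin is the world
position of the *center* of voxel (0, 0, 0).  Masks are boolean arrays;
voxel membership is decided by a voxel-center inclusion test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, GridMismatchError

__all__ = [
    "VoxelGrid",
    "ellipsoid_mask",
    "spheroid_mask",
    "cylinder_mask",
    "mask_centroid",
    "check_same_grid",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of all fields: shape, spacing (mm/voxel) and world origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise GeometryError(f"shape must be 3 positive integers, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be positive on every axis, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # ------------------------------------------------------------------ geometry
    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid box (voxel extents included)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_world(self) -> np.ndarray:
        """World position of the geometric center of the grid box."""
        return self.voxel_to_world(np.array([(n - 1) / 2.0 for n in self.shape]))

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine (axis-aligned, mm)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_voxel(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axes_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            np.arange(n) * s + o
            for n, s, o in zip(self.shape, self.spacing, self.origin)
        )

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) world-coordinate arrays of voxel centers."""
        ax, ay, az = self.axes_world()
        return ax[:, None, None], ay[None, :, None], az[None, None, :]

    def contains_world(self, point, margin_mm: float = 0.0) -> bool:
        """Whether a world point lies within the grid box (voxel extents)."""
        p = np.asarray(point, dtype=float)
        lo = np.asarray(self.origin) - np.asarray(self.spacing) / 2.0 + margin_mm
        hi = lo + np.asarray(self.extent_mm) - 2.0 * margin_mm
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def check_same_grid(grid_a: VoxelGrid, grid_b: VoxelGrid) -> None:
    if not grid_a.same_geometry(grid_b):
        raise GridMismatchError(f"grids differ: {grid_a} vs {grid_b}")


# ---------------------------------------------------------------------- shapes
def ellipsoid_mask(grid: VoxelGrid, center, semi_axes) -> np.ndarray:
    """Axis-aligned ellipsoid by voxel-center inclusion."""
    c = np.asarray(center, dtype=float)
    a = np.asarray(semi_axes, dtype=float)
    if np.any(a <= 0):
        raise GeometryError(f"semi-axes must be positive, got {a}")
    x, y, z = grid.coordinate_arrays()
    q = ((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2 + ((z - c[2]) / a[2]) ** 2
    return q <= 1.0


def spheroid_mask(grid: VoxelGrid, center, axis, length_mm: float, diameter_mm: float) -> np.ndarray:
    """Prolate/oblate spheroid with symmetry `axis`: extent `length_mm` along the
    axis and `diameter_mm` across it.  Used for manufacturer reference ellipsoids."""
    c = np.asarray(center, dtype=float)
    u = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise GeometryError("axis must be a nonzero vector")
    u = u / nrm
    if length_mm <= 0 or diameter_mm <= 0:
        raise GeometryError("length and diameter must be positive")
    x, y, z = grid.coordinate_arrays()
    dx, dy, dz = x - c[0], y - c[1], z - c[2]
    s = dx * u[0] + dy * u[1] + dz * u[2]          # axial offset
    r2 = dx * dx + dy * dy + dz * dz - s * s        # squared radial offset
    ha = length_mm / 2.0
    hb = diameter_mm / 2.0
    return (s / ha) ** 2 + r2 / hb**2 <= 1.0


def cylinder_mask(grid: VoxelGrid, p0, p1, radius_mm: float) -> np.ndarray:
    """Finite cylinder (capsule without end caps beyond segment) of given radius
    around the segment p0-p1, restricted to its bounding box for speed."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if radius_mm <= 0:
        raise GeometryError("radius must be positive")
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    mask = np.zeros(grid.shape, dtype=bool)

    lo_w = np.minimum(p0, p1) - radius_mm
    hi_w = np.maximum(p0, p1) + radius_mm
    lo = np.maximum(np.floor(grid.world_to_voxel(lo_w)).astype(int), 0)
    hi = np.minimum(np.ceil(grid.world_to_voxel(hi_w)).astype(int) + 1,
                    np.asarray(grid.shape))
    if np.any(lo >= hi):
        return mask

    ax, ay, az = grid.axes_world()
    x = ax[lo[0]:hi[0], None, None]
    y = ay[None, lo[1]:hi[1], None]
    z = az[None, None, lo[2]:hi[2]]
    dx, dy, dz = x - p0[0], y - p0[1], z - p0[2]
    if seg_len2 == 0.0:
        r2 = dx * dx + dy * dy + dz * dz
        sub = r2 <= radius_mm**2
    else:
        t = (dx * seg[0] + dy * seg[1] + dz * seg[2]) / seg_len2
        inside_axial = (t >= 0.0) & (t <= 1.0)
        r2 = (dx - t * seg[0]) ** 2 + (dy - t * seg[1]) ** 2 + (dz - t * seg[2]) ** 2
        sub = inside_axial & (r2 <= radius_mm**2)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return mask


def mask_centroid(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """World-coordinate centroid of a nonempty mask."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise GeometryError("centroid of empty mask is undefined")
    return grid.voxel_to_world(idx.mean(axis=0))
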