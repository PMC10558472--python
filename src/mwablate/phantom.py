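"""Synthetic liver/vessel phantoms for exercising the planning pipeline.

No clinical dataset ships with the package, so every downstream stage is
validated on phantoms: voxelized ellipsoidal livers, recursively
bifurcating vessel trees with Murray's-law radius decay, applicator
plans with power/duration settings, ground-truth ablations distorted by
vessel heat-sink indentation, and the two confounders seen in
retrospective clinical analyses — applicator misalignment (registration
error) and infarction wedges stretching from the ablation zone to the
liver capsule.

Every operation is a pure function of its arguments and a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConvergenceError, GeometryError
from .grid import VoxelGrid, cylinder_mask, ellipsoid_mask, mask_centroid

__all__ = [
    "ApplicatorPlan",
    "VesselSegment",
    "PhantomCase",
    "CohortConfig",
    "make_liver_phantom",
    "grow_vessel_tree",
    "synthesize_ground_truth",
    "inject_infarction_wedge",
    "perturb_alignment",
    "sample_cohort",
]


@dataclass(frozen=True)
class ApplicatorPlan:
    """Applicator pose: tip and insertion direction in world mm.

    ``direction`` points from the shaft toward the tip; the active zone
    spans the last ``active_zone_length`` mm of the shaft ending at the tip.
    """

    tip: tuple[float, float, float]
    direction: tuple[float, float, float]
    active_zone_length: float = 14.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        nrm = float(np.linalg.norm(d))
        if abs(nrm - 1.0) > 1e-9:
            if nrm == 0:
                raise GeometryError("direction must be a nonzero vector")
            d = d / nrm
        object.__setattr__(self, "direction", tuple(d))
        object.__setattr__(self, "tip", tuple(float(v) for v in self.tip))
        if self.active_zone_length <= 0:
            raise GeometryError("active zone length must be positive")

    @property
    def active_zone_center(self) -> np.ndarray:
        return np.asarray(self.tip) - np.asarray(self.direction) * self.active_zone_length / 2.0

    @property
    def active_zone_segment(self) -> tuple[np.ndarray, np.ndarray]:
        tip = np.asarray(self.tip)
        return tip - np.asarray(self.direction) * self.active_zone_length, tip


@dataclass(frozen=True)
class VesselSegment:
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius_mm: float
    parent: int  # index into the segment list, -1 for the root


@dataclass
class PhantomCase:
    """A synthetic patient case: anatomy, plans, settings, optional truth."""

    grid: VoxelGrid
    liver_mask: np.ndarray
    vessel_mask: np.ndarray
    vessel_graph: list[VesselSegment] = field(default_factory=list)
    plans: list[ApplicatorPlan] = field(default_factory=list)
    settings: list[tuple[float, float]] = field(default_factory=list)  # (W, s)
    ground_truth_mask: np.ndarray | None = None
    seed: int = 0
    case_id: str = "case"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.liver_mask.shape != self.grid.shape:
            raise GeometryError("liver mask does not match grid")
        if self.vessel_mask.shape != self.grid.shape:
            raise GeometryError("vessel mask does not match grid")
        if np.any(self.vessel_mask & ~self.liver_mask):
            raise GeometryError("vessel mask must be contained in the liver mask")
        if len(self.settings) != len(self.plans):
            raise GeometryError("settings and plans must have equal length")

    def replace(self, **kw) -> "PhantomCase":
        return dataclasses.replace(self, **kw)


# ------------------------------------------------------------------ liver
def make_liver_phantom(semi_axes_mm, grid: VoxelGrid, seed: int = 0,
                       center=None) -> PhantomCase:
    """Voxelized ellipsoidal liver centered in the grid (or at ``center``)."""
    a = np.asarray(semi_axes_mm, dtype=float)
    if np.any(a <= 2.0 * np.asarray(grid.spacing)):
        raise GeometryError("semi-axes must exceed twice the voxel spacing")
    c = grid.center_world if center is None else np.asarray(center, dtype=float)
    lo = c - a
    hi = c + a
    if not (grid.contains_world(lo) and grid.contains_world(hi)):
        raise GeometryError("liver ellipsoid exceeds grid bounds")
    liver = ellipsoid_mask(grid, c, a)
    return PhantomCase(
        grid=grid,
        liver_mask=liver,
        vessel_mask=np.zeros(grid.shape, dtype=bool),
        seed=int(seed),
    )


# ------------------------------------------------------------------ vessels
_MURRAY_EXP = 3.0  # r_parent^3 = sum r_child^3


def _tree_segments(root_point, root_dir, root_radius, root_length,
                   n_generations, seed) -> list[VesselSegment]:
    """Recursive symmetric-ish bifurcation; per-branch RNG streams derived
    from the branch path keep shallow generations identical when deeper
    trees are requested."""
    segments: list[VesselSegment] = []

    def grow(p0, direction, radius, length, gen, parent, path):
        rng = np.random.default_rng(np.random.SeedSequence((seed, *path)))
        p1 = np.asarray(p0) + np.asarray(direction) * length
        segments.append(VesselSegment(tuple(p0), tuple(p1), float(radius), parent))
        idx = len(segments) - 1
        if gen >= n_generations or radius < 0.55:
            return
        child_r = radius / 2.0 ** (1.0 / _MURRAY_EXP)  # symmetric Murray split
        # branch plane: random perpendicular, jittered opening angles ~35 deg
        d = np.asarray(direction)
        helper = rng.normal(size=3)
        perp = np.cross(d, helper)
        perp /= max(np.linalg.norm(perp), 1e-12)
        for k, sign in enumerate((1.0, -1.0)):
            angle = np.deg2rad(35.0 + rng.uniform(-10.0, 10.0))
            new_dir = np.cos(angle) * d + np.sin(angle) * sign * perp
            new_dir /= np.linalg.norm(new_dir)
            grow(p1, new_dir, child_r, length * 0.75, gen + 1, idx, (*path, k))

    grow(np.asarray(root_point, float), np.asarray(root_dir, float),
         float(root_radius), float(root_length), 0, -1, (0,))
    return segments


def _voxelize_segments(segments, grid: VoxelGrid, liver_mask) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    for seg in segments:
        mask |= cylinder_mask(grid, seg.p0, seg.p1, seg.radius_mm)
    return mask & liver_mask


def grow_vessel_tree(
    case: PhantomCase,
    root_point,
    root_radius_mm: float = 3.0,
    n_generations: int = 4,
    target_vascular_fraction: float | None = None,
    seed: int = 0,
    root_length_mm: float = 35.0,
    table=None,
    keepout_margin_mm: float = 8.0,
    max_iter: int = 40,
) -> PhantomCase:
    """Grow a bifurcating vessel tree inside the liver.

    Child radii follow Murray's law (r_p^3 = sum r_c^3) with symmetric
    splits and seed-jittered branch angles; branches are clipped to the
    liver.  When ``target_vascular_fraction`` is given, the tree near the
    first applicator plan is iterated — a feeder branch crossing the
    manufacturer reference ellipsoid has its radius bisected — until the
    vascular-fraction metric is within +-1 percentage point of target.
    """
    root = np.asarray(root_point, dtype=float)
    root_vox = np.round(case.grid.world_to_voxel(root)).astype(int)
    if (np.any(root_vox < 0) or np.any(root_vox >= np.asarray(case.grid.shape))
            or not case.liver_mask[tuple(root_vox)]):
        raise GeometryError("vessel root must lie inside the liver")
    if root_radius_mm < 0.5:
        raise GeometryError("root radius must be >= 0.5 mm")

    liver_c = mask_centroid(case.liver_mask, case.grid)
    root_dir = liver_c - root
    nrm = np.linalg.norm(root_dir)
    root_dir = root_dir / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])

    segments = _tree_segments(root, root_dir, root_radius_mm, root_length_mm,
                              n_generations, seed)

    if target_vascular_fraction is None:
        mask = _voxelize_segments(segments, case.grid, case.liver_mask)
        return case.replace(vessel_mask=mask, vessel_graph=segments)

    # --- targeted growth near the first applicator -------------------------
    from . import applicator as _app
    from . import metrics as _metrics

    if not case.plans:
        raise GeometryError("target fraction requires an applicator plan on the case")
    if table is None:
        table = _app.default_table()
    plan = case.plans[0]
    power_w, duration_s = case.settings[0]
    length_mm, diameter_mm = _app.manufacturer_lookup(table, power_w, duration_s)

    # keep the background tree out of the reference ellipsoid neighbourhood so
    # the feeder branch alone controls the vascular fraction
    keep_r = max(length_mm, diameter_mm) / 2.0 + keepout_margin_mm
    zone_c = plan.active_zone_center
    kept = [s for s in segments
            if _segment_point_distance(s.p0, s.p1, zone_c) > keep_r + s.radius_mm]
    base_mask = _voxelize_segments(kept, case.grid, case.liver_mask)

    def fraction_with(radius: float | None):
        if radius is None:
            return base_mask, kept, _metrics.vascular_fraction(
                base_mask, plan, power_w, duration_s, table, case.grid)
        feeder = _feeder_segment(plan, diameter_mm, radius, seed)
        mask = base_mask | (cylinder_mask(case.grid, feeder.p0, feeder.p1, radius)
                            & case.liver_mask)
        segs = kept + [dataclasses.replace(feeder, radius_mm=radius)]
        return mask, segs, _metrics.vascular_fraction(
            mask, plan, power_w, duration_s, table, case.grid)

    tol = 0.01
    mask0, segs0, f0 = fraction_with(None)
    if target_vascular_fraction <= f0 + tol:
        return case.replace(vessel_mask=mask0, vessel_graph=segs0)

    lo, hi = 0.5, max(diameter_mm, 10.0)
    _, _, f_hi = fraction_with(hi)
    if f_hi + tol < target_vascular_fraction:
        raise ConvergenceError(
            f"target vascular fraction {target_vascular_fraction:.3f} unattainable "
            f"(max achievable {f_hi:.3f})"
        )
    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        mask, segs, f = fraction_with(mid)
        if abs(f - target_vascular_fraction) <= tol:
            best = (mask, segs)
            break
        if f < target_vascular_fraction:
            lo = mid
        else:
            hi = mid
    if best is None:
        raise ConvergenceError(
            f"vascular fraction did not converge to {target_vascular_fraction:.3f} "
            f"within {max_iter} bisection iterations (last {f:.3f})"
        )
    mask, segs = best
    return case.replace(vessel_mask=mask, vessel_graph=segs)


def _segment_point_distance(p0, p1, point) -> float:
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    q = np.asarray(point, float)
    seg = p1 - p0
    l2 = float(seg @ seg)
    t = 0.0 if l2 == 0 else float(np.clip((q - p0) @ seg / l2, 0.0, 1.0))
    return float(np.linalg.norm(q - (p0 + t * seg)))


def _feeder_segment(plan: ApplicatorPlan, diameter_mm, radius, seed) -> VesselSegment:
    """Straight vessel crossing the reference ellipsoid, offset sideways from
    the active-zone center, perpendicular to the applicator axis."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 9173)))
    u = np.asarray(plan.direction)
    helper = rng.normal(size=3)
    v = np.cross(u, helper)
    v /= max(np.linalg.norm(v), 1e-12)
    w = np.cross(u, v)
    center = plan.active_zone_center + v * diameter_mm * 0.15
    half_len = diameter_mm * 1.5
    return VesselSegment(tuple(center - w * half_len), tuple(center + w * half_len),
                         float(radius), -1)


# ------------------------------------------------------------- ground truth
def synthesize_ground_truth(
    case: PhantomCase,
    predicted_mask: np.ndarray,
    distortion: str = "vessel_indent",
    seed: int = 0,
    indent_depth_mm: float = 3.0,
) -> PhantomCase:
    """Fabricate a ground-truth ablation from a predicted mask.

    ``none`` copies the prediction; ``vessel_indent`` erodes the
    prediction wherever it lies within ``indent_depth_mm`` of a vessel,
    emulating the heat-sink indentation seen on post-ablation imaging.
    This is a fixture device, not a physical claim.
    """
    if predicted_mask.shape != case.grid.shape:
        raise GeometryError("predicted mask does not match case grid")
    if distortion not in ("none", "vessel_indent"):
        raise ValueError(f"unknown distortion {distortion!r}")
    gt = predicted_mask.copy()
    if distortion == "vessel_indent" and case.vessel_mask.any():
        dist = ndimage.distance_transform_edt(~case.vessel_mask,
                                              sampling=case.grid.spacing)
        gt &= dist > indent_depth_mm
    gt &= case.liver_mask
    return case.replace(ground_truth_mask=gt)


def inject_infarction_wedge(
    case: PhantomCase,
    apex,
    seed: int = 0,
    half_angle_deg: float = 12.0,
    reach_margin_mm: float = 6.0,
) -> PhantomCase:
    """Union a triangular infarction wedge into the ground truth.

    The wedge is a cone from ``apex`` (a point on the ground-truth
    surface) toward the nearest liver-capsule point, clipped to the
    liver — mimicking the hypodense infarct that inflates the apparent
    ablation on post-procedural imaging when a vessel branch occludes.
    """
    if case.ground_truth_mask is None:
        raise GeometryError("case has no ground-truth mask")
    gt = case.ground_truth_mask
    apex = np.asarray(apex, dtype=float)

    surface = gt & ~ndimage.binary_erosion(gt)
    dist_to_surface = ndimage.distance_transform_edt(~surface, sampling=case.grid.spacing)
    apex_vox = np.clip(np.round(case.grid.world_to_voxel(apex)).astype(int),
                       0, np.asarray(case.grid.shape) - 1)
    if dist_to_surface[tuple(apex_vox)] > 1.5 * max(case.grid.spacing):
        raise GeometryError("wedge apex must lie on the ground-truth surface")

    capsule = case.liver_mask & ~ndimage.binary_erosion(case.liver_mask)
    cap_idx = np.argwhere(capsule)
    cap_pts = case.grid.voxel_to_world(cap_idx)
    nearest = cap_pts[np.argmin(np.linalg.norm(cap_pts - apex, axis=1))]
    axis = nearest - apex
    axis_len = float(np.linalg.norm(axis))
    if axis_len == 0 or half_angle_deg <= 0:
        return case.replace(ground_truth_mask=gt.copy())
    axis /= axis_len

    x, y, z = case.grid.coordinate_arrays()
    dx, dy, dz = x - apex[0], y - apex[1], z - apex[2]
    s = dx * axis[0] + dy * axis[1] + dz * axis[2]
    r2 = np.maximum(dx * dx + dy * dy + dz * dz - s * s, 0.0)
    with np.errstate(invalid="ignore"):
        cone = (s >= 0) & (s <= axis_len + reach_margin_mm) \
            & (np.sqrt(r2) <= s * np.tan(np.deg2rad(half_angle_deg)))
    new_gt = (gt | cone) & case.liver_mask
    return case.replace(ground_truth_mask=new_gt,
                        flags={**case.flags, "gt_overestimated": True})


# ------------------------------------------------------------- misalignment
def perturb_alignment(mask: np.ndarray, translation_mm, rotation_deg,
                      grid: VoxelGrid) -> np.ndarray:
    """Rigid transform of a mask (registration-error emulation).

    Rotation (xyz Euler angles, degrees) about the grid-box center
    followed by translation; nearest-neighbour resampling, clipped to the
    grid.  ``perturb_alignment(m, -R^-1 t, euler(R^-1))`` inverts it up
    to resampling loss.
    """
    from scipy.spatial.transform import Rotation

    if mask.shape != grid.shape:
        raise GeometryError("mask does not match grid")
    t = np.asarray(translation_mm, dtype=float)
    rot = Rotation.from_euler("xyz", np.asarray(rotation_deg, float), degrees=True)
    if np.allclose(t, 0) and np.allclose(rot.as_matrix(), np.eye(3)):
        return mask.copy()
    c = grid.center_world
    r_inv = rot.inv().as_matrix()
    spacing = np.asarray(grid.spacing)
    # output voxel o -> world p' -> input world p = c + R^-1 (p' - c - t)
    matrix = (r_inv * spacing[None, :]) / spacing[:, None]
    world_shift = r_inv @ (np.asarray(grid.origin) - c - t) + c - np.asarray(grid.origin)
    offset = world_shift / spacing
    out = ndimage.affine_transform(
        mask.astype(np.uint8), matrix, offset=offset, order=0,
        mode="constant", cval=0, output_shape=grid.shape,
    )
    return out.astype(bool)


# ----------------------------------------------------------------- cohort
@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for synthetic cohorts.

    Mirrors the retrospective cohort design: 1-6 overlapping ablations
    per case (mostly 1-2), powers in {80, 90, 100} W with 80 W most
    common, durations 3-10 min, and per-case target vascular fractions
    spanning 0-22.2% with roughly a quarter of cases above the 5%
    heat-sink-relevant threshold.
    """

    spacing_mm: float = 2.0
    liver_semi_axes_mm: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (52.0, 44.0, 38.0), (64.0, 54.0, 46.0))  # (low, high) uniform ranges
    margin_mm: float = 12.0
    n_ablation_choices: tuple[int, ...] = (1, 2, 3, 6)
    n_ablation_weights: tuple[float, ...] = (0.40, 0.40, 0.15, 0.05)
    powers_w: tuple[float, ...] = (80.0, 90.0, 100.0)
    power_weights: tuple[float, ...] = (0.6, 0.2, 0.2)
    duration_min_range: tuple[int, int] = (3, 10)
    vf_high_rate: float = 0.25
    vf_high_range: tuple[float, float] = (0.05, 0.222)
    vf_low_range: tuple[float, float] = (0.0, 0.05)
    misalignment_rate: float = 0.10
    wedge_rate: float = 0.15
    misalignment_translation_mm: float = 6.0
    misalignment_rotation_deg: float = 5.0
    active_zone_length_mm: float = 14.0
    placement_radius_frac: float = 0.40
    ablation_spacing_mm: tuple[float, float] = (10.0, 16.0)
    vessel_root_radius_mm: float = 3.0
    vessel_generations: int = 3


def _case_grid(semi_axes, spacing, margin) -> VoxelGrid:
    extent = 2.0 * np.asarray(semi_axes) + 2.0 * margin
    shape = tuple(int(np.ceil(e / spacing)) for e in extent)
    return VoxelGrid(shape, (spacing,) * 3, (0.0, 0.0, 0.0))


def sample_cohort(n_cases: int, seed: int, config: CohortConfig | None = None,
                  table=None) -> list[PhantomCase]:
    """Draw a reproducible synthetic cohort of phantom cases."""
    from . import applicator as _app

    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if config is None:
        config = CohortConfig()
    if table is None:
        table = _app.default_table()

    cases = []
    for i in range(n_cases):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        case_seed = int(rng.integers(0, 2**31 - 1))
        lo, hi = np.asarray(config.liver_semi_axes_mm[0]), np.asarray(config.liver_semi_axes_mm[1])
        semi_axes = rng.uniform(lo, hi)
        grid = _case_grid(semi_axes, config.spacing_mm, config.margin_mm)
        case = make_liver_phantom(semi_axes, grid, seed=case_seed)
        liver_c = grid.center_world

        n_abl = int(rng.choice(config.n_ablation_choices, p=config.n_ablation_weights))
        # first active-zone center well inside the liver, extra ablations
        # clustered around it (overlapping-ablation pattern)
        frac = config.placement_radius_frac
        first = liver_c + rng.uniform(-frac, frac, 3) * semi_axes * 0.8
        centers = [first]
        for _ in range(n_abl - 1):
            step = rng.uniform(*config.ablation_spacing_mm)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = centers[-1] + d * step
            # keep within the safe interior
            rel = (cand - liver_c) / semi_axes
            if np.linalg.norm(rel) > 0.55:
                cand = centers[-1] - d * step
            centers.append(cand)

        plans = []
        settings = []
        for c in centers:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            tip = c + d * config.active_zone_length_mm / 2.0
            plans.append(ApplicatorPlan(tuple(tip), tuple(d),
                                        config.active_zone_length_mm))
            power = float(rng.choice(config.powers_w, p=config.power_weights))
            dur_min = int(rng.integers(config.duration_min_range[0],
                                       config.duration_min_range[1] + 1))
            settings.append((power, float(dur_min * 60)))
        case = case.replace(plans=plans, settings=settings, case_id=f"C{i:03d}")

        if rng.uniform() < config.vf_high_rate:
            target_vf = float(rng.uniform(*config.vf_high_range))
        else:
            target_vf = float(rng.uniform(*config.vf_low_range))
        root = liver_c - np.array([semi_axes[0] * 0.6, 0.0, 0.0])
        case = grow_vessel_tree(
            case, root, config.vessel_root_radius_mm, config.vessel_generations,
            target_vascular_fraction=target_vf, seed=case_seed, table=table,
        )

        flags = {
            "misaligned": bool(rng.uniform() < config.misalignment_rate),
            "gt_overestimated": bool(rng.uniform() < config.wedge_rate),
            "target_vascular_fraction": target_vf,
        }
        if flags["misaligned"]:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            flags["misalignment_translation_mm"] = tuple(
                d * config.misalignment_translation_mm)
            flags["misalignment_rotation_deg"] = tuple(
                rng.uniform(-1, 1, 3) * config.misalignment_rotation_deg)
        case = case.replace(flags=flags)
        cases.append(case)
    return cases
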