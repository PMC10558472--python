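"""Simplified microwave applicator heat source and its calibration.

The deposition model is axisymmetric about the applicator axis: a
Gaussian radial falloff around the active-zone line segment with a
Gaussian axial taper beyond the zone ends, scaled so that the volume
integral equals ``efficiency * power`` at baseline temperature, and
attenuated voxelwise by a temperature-dependent absorption factor that
decays sigmoidally toward a floor across the water evaporation band
(desiccated tissue absorbs poorly).

Calibration fits the free source parameters so that simulated
homogeneous-tissue ablation ellipsoid dimensions reproduce a
manufacturer power/duration table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import CalibrationError, GeometryError, TableRangeError
from .grid import VoxelGrid

__all__ = [
    "SourceParams",
    "ManufacturerTable",
    "absorption_factor",
    "source_geometry_factor",
    "source_field",
    "manufacturer_lookup",
    "calibrate_source",
    "default_table",
    "simulate_homogeneous_ablation",
]

_MM3_TO_M3 = 1e-9


@dataclass(frozen=True)
class SourceParams:
    """Parameters of the simplified deposition model.

    radial_sigma_mm   Gaussian radial scale around the applicator axis.
    axial_taper_mm    Gaussian taper scale beyond the active-zone ends.
    efficiency        fraction of nominal generator power deposited.
    absorption_floor  residual absorption of desiccated tissue, in (0, 1].
    absorption_center_c / absorption_width_c
                      sigmoid midpoint and width of the absorption decay
                      (defaults track the evaporation band).
    """

    radial_sigma_mm: float = 4.5
    axial_taper_mm: float = 3.0
    efficiency: float = 0.7
    absorption_floor: float = 0.2
    absorption_center_c: float = 99.5
    absorption_width_c: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        if self.radial_sigma_mm <= 0 or self.axial_taper_mm <= 0:
            raise ValueError("radial and axial scales must be positive")
        if not 0 < self.absorption_floor <= 1:
            raise ValueError("absorption floor must be in (0, 1]")


def absorption_factor(temp_c, params: SourceParams) -> np.ndarray:
    """Sigmoid decay from 1 toward ``absorption_floor`` across the band."""
    t = np.asarray(temp_c, dtype=float)
    sig = 1.0 / (1.0 + np.exp((t - params.absorption_center_c) / params.absorption_width_c))
    return params.absorption_floor + (1.0 - params.absorption_floor) * sig


def source_geometry_factor(plan, grid: VoxelGrid, params: SourceParams) -> np.ndarray:
    """Normalized deposition shape (1/m^3): integrates to 1 over the grid."""
    u = np.asarray(plan.direction, dtype=float)
    half = plan.active_zone_length / 2.0
    center = np.asarray(plan.active_zone_center, dtype=float)
    if not grid.contains_world(center):
        raise GeometryError("active zone center outside grid")

    x, y, z = grid.coordinate_arrays()
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    s = dx * u[0] + dy * u[1] + dz * u[2]
    r2 = dx * dx + dy * dy + dz * dz - s * s
    axial_excess = np.maximum(np.abs(s) - half, 0.0)
    shape = np.exp(
        -r2 / (2.0 * params.radial_sigma_mm**2)
        - axial_excess**2 / (2.0 * params.axial_taper_mm**2)
    )
    total = float(shape.sum()) * grid.voxel_volume_mm3 * _MM3_TO_M3
    if total <= 0:
        raise GeometryError("deposition shape has zero support on the grid")
    return shape / total


def source_field(plan, power_w: float, temp, params: SourceParams, grid: VoxelGrid) -> np.ndarray:
    """Heat source Q_appl (W/m^3) for the given plan, power and temperature.

    Normalized so the volume integral equals ``efficiency * power`` when the
    temperature is at uniform baseline (absorption ~ 1); hotter voxels are
    attenuated by the absorption factor.
    """
    t_values = temp.values if hasattr(temp, "values") else np.asarray(temp)
    geometry = source_geometry_factor(plan, grid, params)
    return power_w * params.efficiency * geometry * absorption_factor(t_values, params)


# --------------------------------------------------------------- manufacturer
@dataclass(frozen=True)
class ManufacturerTable:
    """Power/duration -> ablation ellipsoid dimensions (length, diameter; mm)."""

    frame: pd.DataFrame  # columns power_w, duration_min, length_mm, diameter_mm

    REQUIRED = ("power_w", "duration_min", "length_mm", "diameter_mm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"table missing columns {missing}")

    @classmethod
    def from_csv(cls, path) -> "ManufacturerTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def powers(self) -> np.ndarray:
        return np.unique(self.frame["power_w"].to_numpy(dtype=float))

    @property
    def durations_min(self) -> np.ndarray:
        return np.unique(self.frame["duration_min"].to_numpy(dtype=float))

    def _regular(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        p = self.powers
        d = self.durations_min
        piv_l = self.frame.pivot_table(index="power_w", columns="duration_min",
                                       values="length_mm")
        piv_d = self.frame.pivot_table(index="power_w", columns="duration_min",
                                       values="diameter_mm")
        if piv_l.isna().any().any():
            raise ValueError("table is not a complete power x duration grid")
        return p, d, piv_l.to_numpy(dtype=float), piv_d.to_numpy(dtype=float)


def manufacturer_lookup(table: ManufacturerTable, power_w: float,
                        duration_s: float) -> tuple[float, float]:
    """Bilinear interpolation of (length, diameter) in (power, duration).

    No extrapolation: out-of-range queries raise :class:`TableRangeError`.
    """
    from scipy.interpolate import RegularGridInterpolator

    duration_min = duration_s / 60.0
    p, d, arr_l, arr_d = table._regular()
    if not (p.min() - 1e-9 <= power_w <= p.max() + 1e-9):
        raise TableRangeError(f"power {power_w} W outside table range [{p.min()}, {p.max()}]")
    if not (d.min() - 1e-9 <= duration_min <= d.max() + 1e-9):
        raise TableRangeError(
            f"duration {duration_min} min outside table range [{d.min()}, {d.max()}]"
        )
    if p.size == 1:
        # single power row: 1D interpolation in duration
        length = float(np.interp(duration_min, d, arr_l[0]))
        diameter = float(np.interp(duration_min, d, arr_d[0]))
        return length, diameter
    query = np.clip([power_w, duration_min], [p.min(), d.min()], [p.max(), d.max()])
    interp_l = RegularGridInterpolator((p, d), arr_l)
    interp_d = RegularGridInterpolator((p, d), arr_d)
    return float(interp_l(query)[0]), float(interp_d(query)[0])


def ellipsoid_volume_ml(length_mm: float, diameter_mm: float) -> float:
    """V = 4/3 pi (L/2)(D/2)^2, returned in millilitres."""
    return (4.0 / 3.0) * np.pi * (length_mm / 2.0) * (diameter_mm / 2.0) ** 2 / 1000.0


def default_table() -> ManufacturerTable:
    """Packaged synthetic table for a 100 W-class applicator.

    The values are *synthetic*: generated by this package's own forward
    model in homogeneous tissue (see ``scripts/make_default_table.py``),
    standing in for vendor ex-vivo specifications which are not public.
    """
    ref = importlib.resources.files("mwablate") / "data" / "manufacturer_table_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        return ManufacturerTable.from_csv(path)


# ---------------------------------------------------------------- calibration
def _calibration_grid(table: ManufacturerTable, spacing_mm: float,
                      active_zone_length: float) -> VoxelGrid:
    max_dim = float(max(table.frame["length_mm"].max(), table.frame["diameter_mm"].max()))
    extent = max_dim + active_zone_length + 50.0  # margin for the 37 degC far field
    n = int(np.ceil(extent / spacing_mm)) | 1     # odd, so a voxel center sits at origin
    half = (n - 1) / 2.0 * spacing_mm
    return VoxelGrid((n, n, n), (spacing_mm,) * 3, (-half, -half, -half))


def simulate_homogeneous_ablation(
    power_w: float,
    duration_s: float,
    params: SourceParams,
    tissue,
    blood,
    grid: VoxelGrid,
    active_zone_length: float = 14.0,
    dt: float | None = None,
    damage_params=None,
    smooth: bool = True,
) -> tuple[float, float]:
    """Single ablation in homogeneous perfused tissue (no vessels); returns
    the predicted ablation (length, diameter) in mm along the z axis."""
    from . import bioheat as _bh
    from . import damage as _dmg

    if damage_params is None:
        damage_params = _dmg.DamageParams()
    axis = np.array([0.0, 0.0, 1.0])
    center = np.zeros(3)
    plan = _plan_on_axis(center, axis, active_zone_length)
    config = _bh.SolverConfig(dt=dt, vessel_sink_enabled=False)

    temp = _bh.TemperatureField.uniform(grid, config.t_init)
    omega_dmg = np.zeros(grid.shape)
    geometry = source_geometry_factor(plan, grid, params)
    if dt is None:
        dt = config.stability_safety * _bh.stability_limit(grid, tissue, blood, blood.omega0)
    n_steps = max(1, int(np.ceil(duration_s / dt)))
    dt = duration_s / n_steps
    gas_term = -damage_params.ea / damage_params.r_gas
    for _ in range(n_steps):
        q = power_w * params.efficiency * geometry * absorption_factor(temp.values, params)
        omega = np.full(grid.shape, blood.omega0) * np.exp(-omega_dmg)
        temp = _bh.step_temperature(temp, q, omega, tissue, blood, config, dt)
        omega_dmg = omega_dmg + dt * damage_params.a_freq * np.exp(
            gas_term / (temp.values + 273.15)
        )
    if smooth:
        return _dmg.smooth_dimensions(omega_dmg, grid, center, axis, damage_params)
    mask = omega_dmg >= damage_params.threshold
    return _dmg.ellipsoid_dimensions(mask, grid, axis)


def _plan_on_axis(center, axis, active_zone_length):
    from .phantom import ApplicatorPlan

    tip = np.asarray(center) + np.asarray(axis) * active_zone_length / 2.0
    return ApplicatorPlan(tip=tuple(tip), direction=tuple(axis),
                          active_zone_length=active_zone_length)


def calibrate_source(
    table: ManufacturerTable,
    tissue,
    blood,
    initial: SourceParams | None = None,
    spacing_mm: float = 2.0,
    active_zone_length: float = 14.0,
    rows: pd.DataFrame | None = None,
    max_nfev: int = 40,
) -> tuple[SourceParams, dict]:
    """Fit (radial_sigma_mm, efficiency) so simulated homogeneous-tissue
    ablation dimensions reproduce the manufacturer table.

    Deterministic least-squares on relative dimension residuals; raises
    :class:`CalibrationError` for underdetermined tables (< 4 rows) or
    residuals that fail to converge.  Returns the fitted params and a fit
    report (per-row residuals, cost, rows used).
    """
    from scipy.optimize import least_squares

    frame = table.frame if rows is None else rows
    if len(frame) < 4:
        raise CalibrationError(
            f"calibration needs >= 4 table rows, got {len(frame)} (underdetermined)"
        )
    if initial is None:
        initial = SourceParams()
    grid = _calibration_grid(table, spacing_mm, active_zone_length)

    targets = frame[["power_w", "duration_min", "length_mm", "diameter_mm"]].to_numpy(float)

    def residuals(x) -> np.ndarray:
        params = replace(initial, radial_sigma_mm=float(x[0]), efficiency=float(x[1]))
        res = []
        for power, dur_min, length, diam in targets:
            sim_l, sim_d = simulate_homogeneous_ablation(
                power, dur_min * 60.0, params, tissue, blood, grid,
                active_zone_length=active_zone_length,
            )
            res.append((sim_l - length) / length)
            res.append((sim_d - diam) / diam)
        return np.asarray(res)

    x0 = np.array([initial.radial_sigma_mm, initial.efficiency])
    fit = least_squares(
        residuals, x0,
        bounds=([1.0, 0.2], [12.0, 1.0]),
        diff_step=0.04, xtol=1e-3, ftol=1e-4, gtol=1e-8, max_nfev=max_nfev,
    )
    if not fit.success and fit.status <= 0:
        raise CalibrationError(f"calibration did not converge: {fit.message}")
    fitted = replace(initial, radial_sigma_mm=float(fit.x[0]), efficiency=float(fit.x[1]))
    final_res = fit.fun.reshape(-1, 2)
    report = {
        "rows_used": len(frame),
        "cost": float(fit.cost),
        "nfev": int(fit.nfev),
        "status": int(fit.status),
        "message": str(fit.message),
        "radial_sigma_mm": fitted.radial_sigma_mm,
        "efficiency": fitted.efficiency,
        "per_row_residuals": [
            {"power_w": float(p), "duration_min": float(d),
             "length_rel_err": float(rl), "diameter_rel_err": float(rd)}
            for (p, d, _, _), (rl, rd) in zip(targets, final_res)
        ],
        "max_abs_rel_residual": float(np.abs(fit.fun).max()),
    }
    if report["max_abs_rel_residual"] > 0.25:
        raise CalibrationError(
            f"calibration residuals too large ({report['max_abs_rel_residual']:.2f}); "
            "the deposition family cannot reproduce this table"
        )
    return fitted, report
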