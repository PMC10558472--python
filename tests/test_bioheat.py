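import numpy as np
import pytest

from mwablate import bioheat as bh
from mwablate import phantom as ph
from mwablate.errors import StabilityError
from mwablate.grid import VoxelGrid, ellipsoid_mask

from conftest import centered_grid

_MM = 1e-3


def slab_grid(n: int, spacing: float) -> VoxelGrid:
    """Quasi-1D grid: Dirichlet ghost centers sit at +-(n+1)/2*spacing."""
    half = (n - 1) / 2.0 * spacing
    return VoxelGrid((n, 1, 1), (spacing, spacing, spacing), (-half, 0.0, 0.0))


def march_to_steady(grid, tissue, blood, omega_value, boundary, t_init, total_time):
    config = bh.SolverConfig(boundary=boundary, t_init=t_init)
    omega = np.full(grid.shape, omega_value)
    q = np.zeros(grid.shape)
    dt = 0.9 * bh.stability_limit(grid, tissue, blood, omega_value)
    temp = bh.TemperatureField.uniform(grid, t_init)
    steps = int(np.ceil(total_time / dt))
    for _ in range(steps):
        temp = bh.step_temperature(temp, q, omega, tissue, blood, config, dt)
    return temp


def slab_analytic(x_mm, half_length_mm, wall_c, tissue, blood, omega):
    """Steady perfused slab with symmetric Dirichlet walls: cosh profile with
    thermal length scale sqrt(lam / (omega rho_b cp_b))."""
    delta = np.sqrt(tissue.lam / (omega * blood.rho_b * blood.cp_b)) / _MM  # mm
    return blood.t_b + (wall_c - blood.t_b) * np.cosh(x_mm / delta) / np.cosh(
        half_length_mm / delta)


def slab_error(n, spacing, tissue, blood, omega=0.0045, wall=80.0, total_time=2500.0):
    grid = slab_grid(n, spacing)
    temp = march_to_steady(grid, tissue, blood, omega, wall, wall, total_time)
    x = grid.axes_world()[0]
    half_length = (n + 1) / 2.0 * spacing
    exact = slab_analytic(x, half_length, wall, tissue, blood, omega)
    return float(np.max(np.abs(temp.values[:, 0, 0] - exact) / np.abs(exact - 0.0)))


class TestEffectiveHeatCapacity:
    def test_baseline_outside_band(self, tissue):
        assert bh.effective_heat_capacity(37.0, tissue) == tissue.cp_base
        assert bh.effective_heat_capacity(150.0, tissue) == tissue.cp_base

    def test_band_integral_equals_latent_heat(self, tissue):
        t_low, t_high = tissue.evaporation_band
        t = np.linspace(t_low, t_high, 2001)
        excess = bh.effective_heat_capacity(t, tissue) - tissue.cp_base
        integral = np.trapezoid(excess, t)
        expected = tissue.water_fraction * tissue.latent_heat
        assert abs(integral - expected) / expected < 1e-9

    def test_enthalpy_inversion_round_trip(self, tissue):
        t = np.linspace(20.0, 150.0, 1301)  # crosses the band
        back = tissue.temperature_from_enthalpy(tissue.specific_enthalpy(t))
        assert np.allclose(back, t, atol=1e-9)


class TestPerfusionField:
    def test_baseline_everywhere_without_vessels(self, blood):
        t = np.full((4, 4, 4), blood.t_b)
        omega = bh.perfusion_field(t, np.zeros_like(t), blood)
        assert np.allclose(omega, blood.omega0)

    def test_vessel_voxels_enhanced_fifty_fold(self, blood):
        t = np.full((4, 4, 4), blood.t_b)
        vessels = np.zeros_like(t, dtype=bool)
        vessels[1, 2, 3] = True
        omega = bh.perfusion_field(t, np.zeros_like(t), blood, vessel_mask=vessels)
        assert omega[1, 2, 3] == pytest.approx(50.0 * blood.omega0)
        assert omega[0, 0, 0] == pytest.approx(blood.omega0)

    def test_perfusion_ceases_with_extreme_damage(self, blood):
        t = np.full((3, 3, 3), blood.t_b)
        damage = np.zeros_like(t)
        damage[1, 1, 1] = 500.0
        omega = bh.perfusion_field(t, damage, blood)
        assert omega[1, 1, 1] < 1e-100

    def test_sink_disabled_ignores_vessels(self, blood):
        t = np.full((3, 3, 3), blood.t_b)
        vessels = np.ones_like(t, dtype=bool)
        omega = bh.perfusion_field(t, np.zeros_like(t), blood,
                                   vessel_mask=vessels, sink_enabled=False)
        assert np.allclose(omega, blood.omega0)


class TestStepTemperature:
    def test_equilibrium_is_preserved(self, tissue, blood):
        grid = centered_grid(9, 1.0)
        config = bh.SolverConfig(boundary=37.0)
        temp = bh.TemperatureField.uniform(grid, 37.0)
        out = bh.step_temperature(temp, np.zeros(grid.shape),
                                  np.zeros(grid.shape), tissue, blood, config, 0.5)
        assert np.allclose(out.values, 37.0, atol=1e-12)

    def test_single_step_perfusion_relaxation_factor(self, tissue, blood):
        # uniform field + insulated box => diffusion term is exactly zero
        grid = centered_grid(5, 1.0)
        config = bh.SolverConfig(boundary="insulated")
        t0 = 50.0
        dt = 0.25
        temp = bh.TemperatureField.uniform(grid, t0)
        omega = np.full(grid.shape, 0.004)
        out = bh.step_temperature(temp, np.zeros(grid.shape), omega,
                                  tissue, blood, config, dt)
        k = 0.004 * blood.rho_b * blood.cp_b / (tissue.rho * tissue.cp_base)
        expected = blood.t_b + (t0 - blood.t_b) * (1.0 - dt * k)
        assert np.allclose(out.values, expected, rtol=1e-12)

    def test_multi_step_relaxation_matches_exact_exponential(self, tissue, blood):
        grid = VoxelGrid((2, 2, 2), (1.0, 1.0, 1.0))
        config = bh.SolverConfig(boundary="insulated")
        t0, total, dt = 60.0, 10.0, 1e-3
        omega_val = 0.0045
        omega = np.full(grid.shape, omega_val)
        temp = bh.TemperatureField.uniform(grid, t0)
        for _ in range(int(total / dt)):
            temp = bh.step_temperature(temp, np.zeros(grid.shape), omega,
                                       tissue, blood, config, dt)
        k = omega_val * blood.rho_b * blood.cp_b / (tissue.rho * tissue.cp_base)
        exact = blood.t_b + (t0 - blood.t_b) * np.exp(-k * total)
        rel_err = abs(temp.values[0, 0, 0] - exact) / abs(exact - blood.t_b)
        assert rel_err < 1e-6

    def test_explicit_stability_violation_raises(self, tissue, blood):
        grid = centered_grid(9, 0.5)
        config = bh.SolverConfig(boundary=37.0)
        temp = bh.TemperatureField.uniform(grid, 37.0)
        dt_max = bh.stability_limit(grid, tissue, blood, 0.0)
        with pytest.raises(StabilityError):
            bh.step_temperature(temp, np.zeros(grid.shape), np.zeros(grid.shape),
                                tissue, blood, config, 3.0 * dt_max)

    def test_maximum_principle_with_nonnegative_source(self, tissue, blood, rng):
        grid = centered_grid(11, 2.0)
        config = bh.SolverConfig(boundary=37.0)
        q = rng.uniform(0, 5e5, grid.shape)
        omega = rng.uniform(0, 0.01, grid.shape)
        temp = bh.TemperatureField.uniform(grid, 37.0)
        dt = 0.5 * bh.stability_limit(grid, tissue, blood, 0.01)
        for _ in range(50):
            temp = bh.step_temperature(temp, q, omega, tissue, blood, config, dt)
            assert temp.values.min() >= 37.0 - 1e-9


class TestSlabAnalytic:
    def test_steady_profile_matches_cosh_solution_at_half_mm(self, tissue, blood):
        # 30 mm perfused slab at 0.5 mm: <1% relative error vs closed form
        err = slab_error(59, 0.5, tissue, blood)
        assert err < 0.01

    def test_second_order_grid_convergence(self, tissue, blood):
        err_coarse = slab_error(14, 2.0, tissue, blood)
        err_fine = slab_error(29, 1.0, tissue, blood)
        assert err_fine < err_coarse / 3.0  # ~4x for a 2nd-order scheme


class TestEnergyBalance:
    def test_adiabatic_enthalpy_rise_equals_deposited_energy(self, tissue, blood):
        from mwablate import applicator as app
        grid = centered_grid(21, 2.0)
        config = bh.SolverConfig(boundary="insulated")
        plan = ph.ApplicatorPlan((0.0, 0.0, 7.0), (0.0, 0.0, 1.0))
        params = app.SourceParams()
        geometry = app.source_geometry_factor(plan, grid, params)
        omega = np.zeros(grid.shape)
        temp = bh.TemperatureField.uniform(grid, 37.0)
        dt = 0.9 * bh.stability_limit(grid, tissue, blood, 0.0)
        voxvol = grid.voxel_volume_mm3 * 1e-9
        deposited = 0.0
        h0 = tissue.rho * tissue.specific_enthalpy(temp.values).sum() * voxvol
        for _ in range(int(180.0 / dt)):
            q = 100.0 * params.efficiency * geometry * app.absorption_factor(
                temp.values, params)
            temp = bh.step_temperature(temp, q, omega, tissue, blood, config, dt)
            deposited += q.sum() * voxvol * dt
        h1 = tissue.rho * tissue.specific_enthalpy(temp.values).sum() * voxvol
        assert temp.values.max() > 100.0  # the band was actually crossed
        assert abs((h1 - h0) - deposited) / deposited < 0.01


class TestImplicitScheme:
    def test_agrees_with_explicit_within_half_degree(self, tissue, blood):
        from mwablate import applicator as app
        grid = centered_grid(15, 2.0)
        plan = ph.ApplicatorPlan((0.0, 0.0, 7.0), (0.0, 0.0, 1.0))
        params = app.SourceParams()
        geometry = app.source_geometry_factor(plan, grid, params)
        omega = np.full(grid.shape, blood.omega0)
        q = 30.0 * params.efficiency * geometry
        dt = 0.25
        results = {}
        for scheme in ("explicit", "implicit"):
            config = bh.SolverConfig(boundary=37.0, scheme=scheme)
            temp = bh.TemperatureField.uniform(grid, 37.0)
            for _ in range(int(30.0 / dt)):
                temp = bh.step_temperature(temp, q, omega, tissue, blood, config, dt)
            results[scheme] = temp.values
        diff = np.abs(results["explicit"] - results["implicit"]).max()
        assert results["explicit"].max() > 45.0  # nontrivial heating
        assert diff < 0.5


class TestSimulate:
    @pytest.fixture
    def small_case(self, table):
        grid = centered_grid(41, 2.0)
        case = ph.make_liver_phantom((36, 36, 36), grid)
        plan = ph.ApplicatorPlan((0.0, 0.0, 7.0), (0.0, 0.0, 1.0))
        return case.replace(plans=[plan], settings=[(100.0, 180.0)])

    def test_zero_power_produces_no_ablation(self, small_case, tissue, blood):
        case = small_case.replace(settings=[(0.0, 180.0)])
        sim = bh.simulate(case, tissue, blood, bh.SolverConfig())
        assert sim.union_mask.sum() == 0
        assert np.allclose(sim.final_temperature.values, 37.0, atol=1e-6)

    def test_typical_settings_produce_nonempty_ablation(self, small_case, tissue, blood):
        sim = bh.simulate(small_case, tissue, blood, bh.SolverConfig())
        assert sim.union_mask.sum() > 0

    def test_vessel_sink_never_enlarges_ablation(self, small_case, tissue, blood):
        vessels = ellipsoid_mask(small_case.grid, (8.0, 0.0, 0.0), (3, 3, 30))
        vessels &= small_case.liver_mask
        case = small_case.replace(vessel_mask=vessels)
        sim_on = bh.simulate(case, tissue, blood,
                             bh.SolverConfig(vessel_sink_enabled=True))
        sim_off = bh.simulate(case, tissue, blood,
                              bh.SolverConfig(vessel_sink_enabled=False))
        assert sim_on.union_mask.sum() < sim_off.union_mask.sum()
        # monotone in enhancement strength as well
        import dataclasses
        blood_weak = dataclasses.replace(blood, vessel_enhancement=5.0)
        sim_weak = bh.simulate(case, tissue, blood_weak,
                               bh.SolverConfig(vessel_sink_enabled=True))
        assert sim_on.union_mask.sum() <= sim_weak.union_mask.sum() <= sim_off.union_mask.sum()

    def test_simulation_is_deterministic(self, small_case, tissue, blood):
        a = bh.simulate(small_case, tissue, blood, bh.SolverConfig())
        b = bh.simulate(small_case, tissue, blood, bh.SolverConfig())
        assert np.array_equal(a.damage_fields[0].omega, b.damage_fields[0].omega)
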