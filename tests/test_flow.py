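import numpy as np
import pytest

from shearclot.flow import (
    FlowSolver,
    FluidState,
    ResistanceParams,
    carman_kozeny_resistance,
    channel_inflow_profile,
    flow_rate_through_plane,
    shear_rate_field,
    step_fluid,
)
from shearclot.grid import BoundaryPatch, build_bleeding_chip_grid, build_channel_grid

MU = 3.5  # mg/(mm s)


def pressure_driven_channel(dx, dp=100.0, length=0.16, height=0.05):
    g = build_channel_grid(length, height, None, dx, mode_2d=True)
    g.patches[0] = BoundaryPatch("inlet", "pressure", axis=0, side="low",
                                 value=dp)
    return g


class TestCarmanKozeny:
    def test_empty_clot(self):
        assert carman_kozeny_resistance(0.0) == 0.0

    def test_full_packing_value(self):
        # theta_B = 1, C_CK = 1e6: 1e6 * 0.36 / 0.4^3 = 5.625e6
        v = carman_kozeny_resistance(1.0, ResistanceParams(1.0e6))
        assert v == pytest.approx(5.625e6, rel=1e-12)

    def test_monotone(self):
        t = np.linspace(0, 1.2, 50)
        a = carman_kozeny_resistance(t)
        assert np.all(np.diff(a) > 0)

    def test_nonphysical_packing_errors(self):
        with pytest.raises(ValueError):
            carman_kozeny_resistance(1.0 / 0.6)


class TestSteadyProfiles:
    def test_poiseuille_profile_within_1pct(self):
        g = pressure_driven_channel(0.0025)
        solver = FlowSolver(g, mu=MU)
        st = solver.solve_steady(np.zeros(g.dims))
        G = 100.0 / 0.16
        y = g.cell_centers(1)
        u_exact = G / (2 * MU) * y * (0.05 - y)
        u_mid = st.velocity[0][g.dims[0] // 2, :]
        assert np.abs(u_mid - u_exact).max() <= 0.01 * u_exact.max()

    def test_brinkman_profile_within_1pct(self):
        g = pressure_driven_channel(0.0025)
        solver = FlowSolver(g, mu=MU)
        a0 = 2000.0
        st = solver.solve_steady(np.full(g.dims, a0))
        G = 100.0 / 0.16
        h = 0.05
        y = g.cell_centers(1)
        sa = np.sqrt(a0)
        u_exact = G / (MU * a0) * (
            1 - np.cosh(sa * (y - h / 2)) / np.cosh(sa * h / 2))
        u_mid = st.velocity[0][g.dims[0] // 2, :]
        assert np.abs(u_mid - u_exact).max() <= 0.01 * u_exact.max()

    def test_second_order_convergence(self):
        errs = []
        for dx in (0.005, 0.0025):
            g = pressure_driven_channel(dx)
            solver = FlowSolver(g, mu=MU)
            a0 = 2000.0
            st = solver.solve_steady(np.full(g.dims, a0))
            G = 100.0 / 0.16
            h = 0.05
            y = g.cell_centers(1)
            sa = np.sqrt(a0)
            u_exact = G / (MU * a0) * (
                1 - np.cosh(sa * (y - h / 2)) / np.cosh(sa * h / 2))
            u_mid = st.velocity[0][g.dims[0] // 2, :]
            errs.append(np.abs(u_mid - u_exact).max() / u_exact.max())
        assert errs[0] / errs[1] > 3.0  # ~4 for 2nd order

    def test_solidified_region_blocks_flow(self):
        g = build_channel_grid(0.16, 0.05, None, 0.005, mode_2d=True)
        prof = channel_inflow_profile(g, 300.0)
        solver = FlowSolver(g, mu=MU)
        alpha = np.zeros(g.dims)
        alpha[12:20, :5] = 1e10  # near-solid clot on the lower half-lumen
        st = solver.solve_steady(alpha, inflow={"inlet": prof})
        inner = np.abs(st.velocity[0][14:18, :4]).max()
        mean_in = np.abs(prof).mean()
        assert inner < 1e-3 * mean_in

    def test_divergence_free(self):
        g = build_channel_grid(0.16, 0.05, None, 0.005, mode_2d=True)
        prof = channel_inflow_profile(g, 300.0)
        solver = FlowSolver(g, mu=MU)
        st = solver.solve_steady(np.zeros(g.dims), inflow={"inlet": prof})
        umax = st.max_speed()
        div = solver.divergence(st)
        assert np.abs(div).max() <= 1e-8 * umax / min(g.spacing)

    def test_increasing_theta_decreases_flow_at_fixed_pressure(self):
        g = pressure_driven_channel(0.005)
        solver = FlowSolver(g, mu=MU)
        flows = []
        for theta in (0.0, 0.2, 0.4, 0.6):
            alpha = carman_kozeny_resistance(np.full(g.dims, theta))
            st = solver.solve_steady(np.asarray(alpha))
            flows.append(flow_rate_through_plane(st, g, 0, 0.08))
        assert np.all(np.diff(flows) < 0)


class TestTransient:
    def test_step_relaxes_to_steady_state(self):
        g = build_channel_grid(0.16, 0.05, None, 0.005, mode_2d=True)
        prof = channel_inflow_profile(g, 300.0)
        solver = FlowSolver(g, mu=MU)
        st = FluidState.zeros(g)
        for _ in range(25):
            st = solver.step(st, np.zeros(g.dims), 5e-4, inflow={"inlet": prof})
        ref = solver.solve_steady(np.zeros(g.dims), inflow={"inlet": prof})
        err = np.abs(st.velocity[0] - ref.velocity[0]).max()
        assert err <= 1e-4 * ref.velocity[0].max()

    def test_cfl_violation_raises(self):
        g = build_channel_grid(0.16, 0.05, None, 0.005, mode_2d=True)
        prof = channel_inflow_profile(g, 300.0)
        st = FluidState.zeros(g)
        st.velocity[0][:] = 50.0
        with pytest.raises(ValueError, match="CFL"):
            step_fluid(st, g, np.zeros(g.dims), dt=0.01, inflow={"inlet": prof})

    def test_divergence_free_after_step(self):
        g = build_channel_grid(0.16, 0.05, None, 0.005, mode_2d=True)
        prof = channel_inflow_profile(g, 300.0)
        solver = FlowSolver(g, mu=MU)
        st = solver.step(FluidState.zeros(g), np.zeros(g.dims), 5e-4,
                         inflow={"inlet": prof})
        assert np.abs(solver.divergence(st)).max() < 1e-6


class TestShearRate:
    def test_simple_shear(self):
        g = build_channel_grid(0.1, 0.05, None, 0.005, mode_2d=True)
        st = FluidState.zeros(g)
        gam0 = 100.0
        y = g.cell_centers(1)
        st.velocity[0][:, :] = gam0 * y[None, :]
        gam = shear_rate_field(st, g)
        # interior cells recover the imposed rate exactly
        assert np.allclose(gam[:, 1:-1], gam0, rtol=1e-9)

    def test_rigid_rotation_zero_shear(self):
        g = build_channel_grid(0.05, 0.05, None, 0.005, mode_2d=True)
        st = FluidState.zeros(g)
        omega = 10.0
        # u = (-omega*y, omega*x) evaluated at the staggered face positions
        yu = g.cell_centers(1)
        st.velocity[0][:, :] = -omega * yu[None, :]
        xv = g.cell_centers(0)
        st.velocity[1][:, :] = omega * xv[:, None]
        gam = shear_rate_field(st, g)
        assert np.abs(gam[1:-1, 1:-1]).max() < 1e-9 * omega

    def test_poiseuille_wall_shear(self):
        g = pressure_driven_channel(0.00125)
        solver = FlowSolver(g, mu=MU)
        st = solver.solve_steady(np.zeros(g.dims))
        G = 100.0 / 0.16
        h = 0.05
        wall_exact = G * h / (2 * MU)
        gam = shear_rate_field(st, g)
        # wall-adjacent cell center sits at dx/2: analytic value there
        dy = g.spacing[1]
        expected = G / (2 * MU) * (h - dy)
        assert gam[g.dims[0] // 2, 0] == pytest.approx(expected, rel=0.02)
        assert abs(gam[g.dims[0] // 2, 0] - wall_exact) < 0.05 * wall_exact


class TestFlowRate:
    def test_plug_flow_arithmetic(self):
        g = build_channel_grid(0.1, 0.05, 0.05, 0.005, mode_2d=False)
        st = FluidState.zeros(g)
        st.velocity[0][:] = 1.0  # mm/s
        q = flow_rate_through_plane(st, g, 0, 0.05)
        # 1 mm/s * 0.05*0.05 mm^2 = 2.5e-3 mm^3/s = 0.15 uL/min
        assert q == pytest.approx(0.15, rel=1e-12)

    def test_zero_velocity(self):
        g = build_channel_grid(0.1, 0.05, None, 0.005, mode_2d=True)
        q = flow_rate_through_plane(FluidState.zeros(g), g, 0, 0.05)
        assert q == 0.0

    def test_conservation_between_planes(self):
        g = build_channel_grid(0.16, 0.05, None, 0.0025, mode_2d=True)
        prof = channel_inflow_profile(g, 300.0)
        solver = FlowSolver(g, mu=MU)
        st = solver.solve_steady(np.zeros(g.dims), inflow={"inlet": prof})
        q1 = flow_rate_through_plane(st, g, 0, 0.04)
        q2 = flow_rate_through_plane(st, g, 0, 0.12)
        assert q2 == pytest.approx(q1, rel=0.005)

    def test_solid_plane_errors(self):
        g = build_bleeding_chip_grid((0.3, 0.05, 0.05), (0.3, 0.1, 0.05),
                                     (0.08, 0.03, 0.05), 0.005)
        st = FluidState.zeros(g)
        region = np.zeros(g.dims, dtype=bool)
        region[0, :] = True  # x-slab far from the injury channel
        with pytest.raises(ValueError):
            flow_rate_through_plane(st, g, 1, 0.12, region=region)
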