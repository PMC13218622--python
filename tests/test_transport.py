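import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from shearclot.flow import FluidState, channel_inflow_profile
from shearclot.grid import build_channel_grid
from shearclot.kinetics import SPECIES, PlateletFields, default_params
from shearclot.transport import (
    TransportWorkspace,
    advect_diffuse_species,
    step_species,
    virtual_substance,
)
from shearclot.wellmixed import _STATE, simulate_wellmixed, wellmixed_rhs


def closed_box(n=20, dx=0.005):
    """Grid with no openings (all walls): every boundary face is no-slip."""
    g = build_channel_grid(n * dx, n * dx, None, dx, mode_2d=True)
    g.patches = []
    return g


class TestVirtualSubstance:
    def test_zero_field(self):
        g = closed_box()
        eta = virtual_substance(np.zeros(g.dims), 2.5e-5, 0.36, g)
        assert np.all(eta == 0.0)

    def test_uniform_field_invariant(self):
        g = closed_box()
        eta = virtual_substance(np.full(g.dims, 0.3), 2.5e-5, 0.36, g)
        assert np.allclose(eta, 0.3, rtol=1e-10)

    def test_zero_kappa_identity(self):
        g = closed_box()
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 1, g.dims)
        assert np.array_equal(virtual_substance(theta, 2.5e-5, 0.0, g), theta)

    def test_single_cell_spread_matches_matrix_exponential(self):
        """Implicit one-step diffusion against the dense expm oracle (1D chain)."""
        g = build_channel_grid(0.05, 0.005, None, 0.005, mode_2d=True)
        g.patches = []
        n = g.dims[0]
        theta = np.zeros(g.dims)
        theta[n // 2, 0] = 1.0
        D, tau = 2.5e-5, (0.003) ** 2 / 2.5e-5
        eta = virtual_substance(theta, D, tau, g)
        # mass conserved
        assert eta.sum() == pytest.approx(1.0, rel=1e-8)
        # oracle: exact exponential of the 1D Neumann Laplacian
        h = g.spacing[0]
        L = np.zeros((n, n))
        for i in range(n):
            if i > 0:
                L[i, i - 1] = 1
                L[i, i] -= 1
            if i < n - 1:
                L[i, i + 1] = 1
                L[i, i] -= 1
        ref = expm(D * tau / h**2 * L) @ theta[:, 0]
        # one implicit Euler step approximates the heat kernel: same mass,
        # same center, comparable spread
        sd_eta = np.sqrt(np.sum(eta[:, 0] * (np.arange(n) - n // 2) ** 2))
        sd_ref = np.sqrt(np.sum(ref * (np.arange(n) - n // 2) ** 2))
        assert sd_eta == pytest.approx(sd_ref, rel=0.35)
        assert sd_eta * h == pytest.approx(0.003, rel=0.5)

    def test_negative_theta_rejected(self):
        g = closed_box()
        with pytest.raises(ValueError):
            virtual_substance(np.full(g.dims, -0.1), 2.5e-5, 0.1, g)


class TestAdvectionDiffusion:
    def test_closed_box_diffusion_conserves_mass(self):
        g = closed_box()
        vel = tuple(np.zeros(s) for s in
                    [(g.dims[0] + 1, g.dims[1]), (g.dims[0], g.dims[1] + 1)])
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 1e5, g.dims)
        total0 = f.sum()
        for _ in range(50):
            f = advect_diffuse_species(f, vel, 2.5e-5, np.zeros(g.dims),
                                       0.05, g)
        assert f.sum() == pytest.approx(total0, rel=1e-12)

    def test_full_hindrance_freezes_field(self):
        g = closed_box()
        vel = (np.ones((g.dims[0] + 1, g.dims[1])),
               np.zeros((g.dims[0], g.dims[1] + 1)))
        rng = np.random.default_rng(2)
        f0 = rng.uniform(0, 1e5, g.dims)
        f = advect_diffuse_species(f0, vel, 2.5e-5, np.ones(g.dims), 1e-3, g)
        assert np.allclose(f, f0)

    def test_gaussian_pulse_advection_diffusion(self):
        """1D pulse in uniform flow: center moves at u*t, variance grows 2Dt."""
        dx = 0.00025
        g = build_channel_grid(0.4, 2 * dx, None, dx, mode_2d=True)
        x = g.cell_centers(0)
        u, D = 1.0, 2.5e-4
        sigma0 = 0.02
        f = np.exp(-((x - 0.1) ** 2) / (2 * sigma0**2))[:, None] * np.ones(
            (1, g.dims[1]))
        vel = (np.full((g.dims[0] + 1, g.dims[1]), u),
               np.zeros((g.dims[0], g.dims[1] + 1)))
        t = 0.0
        dt = 0.6 / (u / dx + 4 * D / dx**2)
        T = 0.15
        while t < T - 1e-12:
            step = min(dt, T - t)
            f = advect_diffuse_species(f, vel, D, np.zeros(g.dims), step, g,
                                       inlet_values={"inlet": 0.0})
            t += step
        prof = f[:, 0]
        m = prof.sum()
        mean = (x * prof).sum() / m
        var = ((x - mean) ** 2 * prof).sum() / m
        assert mean == pytest.approx(0.1 + u * T, abs=0.02 * (0.1 + u * T))
        assert var == pytest.approx(sigma0**2 + 2 * D * T, rel=0.02)

    def test_cfl_violation_raises(self):
        g = closed_box()
        vel = (np.full((g.dims[0] + 1, g.dims[1]), 10.0),
               np.zeros((g.dims[0], g.dims[1] + 1)))
        with pytest.raises(ValueError, match="CFL"):
            advect_diffuse_species(np.ones(g.dims), vel, 0.0,
                                   np.zeros(g.dims), 0.01, g)


class TestStepSpecies:
    def _setup(self, params):
        g = build_channel_grid(0.08, 0.04, None, 0.005, mode_2d=True)
        prof = channel_inflow_profile(g, 300.0)
        vel = (np.zeros((g.dims[0] + 1, g.dims[1])),
               np.zeros((g.dims[0], g.dims[1] + 1)))
        fields = PlateletFields.zeros(g.dims, params.P_max)
        return g, vel, fields

    def test_zero_kinetics_reduces_to_transport(self, params):
        from dataclasses import replace

        from shearclot.kinetics import RateFunction

        zero = RateFunction("constant", a=0.0, b=0.0)
        p = replace(params, k_adh_vwf_on=zero, k_adh_vwf_off=zero,
                    k_coh_vwf_on=zero, k_coh_vwf_off=zero, k_act_vwf=zero,
                    k_adh_col=0.0, k_coh_fbg=0.0, k_act_col=0.0,
                    adp_act_rate=0.0, adp_release_total=0.0)
        g, vel, fields = self._setup(p)
        rng = np.random.default_rng(3)
        fields.P_mu[:] = rng.uniform(0, 1e5, g.dims)
        ref = advect_diffuse_species(fields.P_mu, vel, p.D_P, fields.theta_T,
                                     1e-3, g)
        gam = np.full(g.dims, 300.0)
        out = step_species(fields, vel, p, np.zeros(g.dims), 1e-3, g, gam)
        assert np.allclose(out.P_mu, ref, rtol=1e-12)
        assert np.all(out.P_seu == 0)

    def test_reaction_only_matches_stiff_ode_reference(self, params):
        """u=0, D=0, single active cell: the RK4 reaction path must match a
        high-accuracy stiff ODE reference to 1e-6 relative over 10 s."""
        from dataclasses import replace

        p = replace(params, D_P=0.0, D_ADP=0.0)
        g, vel, fields = self._setup(p)
        fields.P_mu[:] = 2.5e5
        H = np.ones(g.dims)
        gam = np.full(g.dims, 1500.0)
        ws = TransportWorkspace()
        dt = 0.01
        t = 0.0
        while t < 10.0 - 1e-9:
            fields = step_species(fields, vel, p, H, dt, g, gam,
                                  workspace=ws, eta_pseudo_dt=0.0)
            t += dt
        # reference: same network as a scalar ODE via solve_ivp (Radau);
        # eta_pseudo_dt=0 makes every cell identical and eta == theta
        y0 = np.zeros(len(_STATE))
        y0[0] = 2.5e5
        ref = solve_ivp(
            wellmixed_rhs, (0, 10.0), y0,
            args=(p, 1500.0, 2.5e5, True, False),
            method="Radau", rtol=1e-10, atol=1e-4)
        yref = ref.y[:, -1]
        ysim = np.array([getattr(fields, n)[0, 0] for n in SPECIES]
                        + [fields.ADP[0, 0], fields.adp_reservoir[0, 0]])
        scale = max(yref.max(), 1.0)
        assert np.abs(ysim - yref).max() <= 1e-6 * scale

    def test_rk4_fourth_order_convergence(self, params):
        """Halving the reaction sub-step shrinks the error ~16x."""
        from dataclasses import replace

        p = replace(params, D_P=0.0, D_ADP=0.0)
        g, vel, _ = self._setup(p)
        gam = np.full(g.dims, 1500.0)
        H = np.ones(g.dims)

        def run(nsub, dt=0.4, T=4.0):
            f = PlateletFields.zeros(g.dims, p.P_max)
            f.P_mu[:] = 2.5e5
            ws = TransportWorkspace()
            t = 0.0
            while t < T - 1e-9:
                f = step_species(f, vel, p, H, dt, g, gam, workspace=ws,
                                 eta_pseudo_dt=0.0, n_reaction_substeps=nsub)
                t += dt
            return np.array([getattr(f, n)[0, 0] for n in SPECIES])

        ref = run(64)
        e1 = np.abs(run(2) - ref).max()
        e2 = np.abs(run(4) - ref).max()
        assert e1 / e2 > 10.0  # 16x for clean 4th order

    def test_global_platelet_budget_closed_box(self, params):
        """Reactions move platelets between species but never create or
        destroy them: the closed-box total is conserved over 1000 steps."""
        g = closed_box(10)
        vel = (np.zeros((g.dims[0] + 1, g.dims[1])),
               np.zeros((g.dims[0], g.dims[1] + 1)))
        rng = np.random.default_rng(5)
        fields = PlateletFields.zeros(g.dims, params.P_max)
        for n in SPECIES:
            getattr(fields, n)[:] = rng.uniform(0, 0.1 * params.P_max, g.dims)
        fields.ADP[:] = rng.uniform(0, 2, g.dims)
        H = np.zeros(g.dims)
        H[:, 0] = 1.0
        gam = np.full(g.dims, 900.0)
        total0 = fields.total_platelets().sum()
        ws = TransportWorkspace()
        for _ in range(1000):
            fields = step_species(fields, vel, params, H, 2e-3, g, gam,
                                  workspace=ws)
        total = fields.total_platelets().sum()
        assert total == pytest.approx(total0, rel=1e-6)
        assert ws.clamped_mass <= 1e-6 * total0 * g.cell_volume


class TestWellMixed:
    def test_monotone_growth_and_saturation(self, params):
        res = simulate_wellmixed(params, 300.0, 30.0, dt=0.01)
        assert np.all(np.diff(res.theta_B) >= -1e-12)
        assert res.theta_B[-1] <= 1.2

    def test_higher_shear_higher_on_rate_grows_faster(self, params):
        lo = simulate_wellmixed(params, 300.0, 20.0, dt=0.01)
        hi = simulate_wellmixed(params, 1500.0, 20.0, dt=0.01)
        assert hi.theta_B[-1] > lo.theta_B[-1]
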