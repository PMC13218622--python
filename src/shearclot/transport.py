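"""Hindered advection–diffusion–reaction transport of platelet species and ADP.

The mobile species (P_mu, P_ma) and ADP move by hindered advection–diffusion:
fluxes are scaled by the hindrance factor W(theta_T) = tanh(pi(1-theta_T)), so
transport shuts off inside a dense aggregate.  Bound species are attached to
the wall or to the clot and do not move.  A fractional-step scheme decouples
transport from the reactions, which are integrated pointwise with RK4 at half
the transport timestep.

Advection uses a conservative, dimension-split, van-Leer-limited upwind flux;
diffusion is an explicit conservative flux (at the diffusivities and
resolutions used here the advective CFL bound is far stricter than the
diffusive one, and the stepper raises if that ordering is violated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import Grid
from .kinetics import (
    MOBILE_SPECIES,
    SPECIES,
    KineticParams,
    PlateletFields,
    RateTable,
    evaluate_rate_table,
    hindrance_W,
    reaction_rhs,
)

__all__ = [
    "virtual_substance",
    "advect_diffuse_species",
    "step_species",
    "TransportWorkspace",
]


def _sl(ndim, axis, s):
    out = [slice(None)] * ndim
    out[axis] = s
    return tuple(out)


# --------------------------------------------------------------------- eta


_eta_cache: dict = {}


def _diffusion_operator(grid: Grid, kappa: float):
    """Factorized (I + kappa * L) with no-flux walls and solid masking.

    kappa = D_eta * pseudo_dt (mm^2).  Cached per (grid id, kappa).
    """
    key = (id(grid), float(kappa))
    if key in _eta_cache:
        return _eta_cache[key]
    nd = grid.ndim
    n = int(np.prod(grid.dims))
    idx = np.arange(n).reshape(grid.dims)
    fluid = grid.fluid
    rows, cols, vals = [], [], []
    diag = np.ones(grid.dims)
    for a in range(nd):
        h = grid.spacing[a]
        c = kappa / h**2
        for sgn in (-1, 1):
            nb_fluid = np.roll(fluid, -sgn, axis=a)
            edge = _edge_mask(grid.dims, a, sgn)
            open_face = fluid & nb_fluid & ~edge
            nb_idx = np.roll(idx, -sgn, axis=a)
            rows.append(idx[open_face])
            cols.append(nb_idx[open_face])
            vals.append(np.full(int(open_face.sum()), -c))
            diag[open_face] += c
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(diag.ravel())
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsc()
    lu = spla.splu(A)
    _eta_cache[key] = lu
    return lu


def _edge_mask(dims, axis, sgn):
    m = np.zeros(dims, dtype=bool)
    m[_sl(len(dims), axis, -1 if sgn > 0 else 0)] = True
    return m


def virtual_substance(theta_field, D_eta: float, pseudo_dt: float,
                      grid: Grid) -> np.ndarray:
    """One implicit diffusion step of a bound-platelet fraction.

    Spreads the pointwise fraction over a length sqrt(D_eta * pseudo_dt)
    (one platelet diameter by default) so that point densities acquire the
    finite interaction neighborhood of a real platelet.  No-flux boundaries;
    the integral over the fluid region is conserved to solver tolerance.
    """
    theta = np.asarray(theta_field, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta_field must be nonnegative")
    kappa = D_eta * pseudo_dt
    if kappa == 0.0:
        return theta.copy()
    lu = _diffusion_operator(grid, kappa)
    rhs = np.where(grid.fluid, theta, 0.0).ravel()
    eta = lu.solve(rhs).reshape(grid.dims)
    return np.maximum(eta, 0.0)


# ----------------------------------------------------------------- transport


def _vanleer(r):
    return (r + np.abs(r)) / (1.0 + np.abs(r))


def advect_diffuse_species(
    fieldv,
    velocity,
    D: float,
    theta_T,
    dt: float,
    grid: Grid,
    inlet_values: dict | None = None,
    hindered: bool = True,
    cfl_limit: float = 1.0,
) -> np.ndarray:
    """Conservative hindered advection–diffusion update of one cell field.

    velocity : tuple of face-normal components (MAC layout, mm/s)
    inlet_values : patch name -> boundary-plane array (or scalar) of the inflow
        concentration; outflow/pressure patches are zero-gradient.
    Raises when the advective CFL (or the explicit diffusive limit) exceeds
    ``cfl_limit``.
    """
    nd = grid.ndim
    f = np.asarray(fieldv, dtype=float)
    fluid = grid.fluid
    W = hindrance_W(np.asarray(theta_T)) if hindered else np.ones(grid.dims)
    umax = max(float(np.abs(v).max()) for v in velocity)
    hmin = min(grid.spacing)
    # combined explicit advection + diffusion stability criterion
    rate = umax / hmin + 2 * nd * D / hmin**2
    if rate > 0 and dt * rate > cfl_limit:
        raise ValueError(
            f"transport stability violation (advective CFL + explicit "
            f"diffusion): dt={dt:g} exceeds {cfl_limit / rate:g} s "
            f"at |u|max={umax:g} mm/s, D={D:g} mm^2/s")

    dfdt = np.zeros_like(f)
    inlet_values = inlet_values or {}
    inflow_patches = {p.name: p for p in grid.patches if p.kind == "inflow"}

    for a in range(nd):
        h = grid.spacing[a]
        n = grid.dims[a]
        u = velocity[a]  # shape: faces along a
        # face hindrance = min of the adjacent cells: a saturated cell shuts
        # off its faces entirely, which is what bounds theta_T near 1
        Wf = np.ones(u.shape)
        Wf[_sl(nd, a, slice(1, n))] = np.minimum(
            W[_sl(nd, a, slice(0, n - 1))], W[_sl(nd, a, slice(1, n))])
        Wf[_sl(nd, a, 0)] = W[_sl(nd, a, 0)]
        Wf[_sl(nd, a, n)] = W[_sl(nd, a, n - 1)]

        flux = np.zeros(u.shape)  # per unit face area

        # --- interior faces: limited upwind advection + central diffusion
        uf = u[_sl(nd, a, slice(1, n))]
        fL = f[_sl(nd, a, slice(0, n - 1))]
        fR = f[_sl(nd, a, slice(1, n))]
        # upwind-biased van Leer reconstruction
        df = fR - fL
        fLL = np.concatenate([f[_sl(nd, a, slice(0, 1))],
                              f[_sl(nd, a, slice(0, n - 2))]], axis=a)
        fRR = np.concatenate([f[_sl(nd, a, slice(2, n))],
                              f[_sl(nd, a, slice(n - 1, n))]], axis=a)
        eps = 1e-300
        r_pos = (fL - fLL) / (np.where(np.abs(df) < eps, eps, df))
        r_neg = (fRR - fR) / (np.where(np.abs(df) < eps, eps, df))
        phi_pos = _vanleer(r_pos)
        phi_neg = _vanleer(r_neg)
        f_face_pos = fL + 0.5 * phi_pos * df
        f_face_neg = fR - 0.5 * phi_neg * df
        f_upw = np.where(uf >= 0, f_face_pos, f_face_neg)
        adv = uf * f_upw
        diff = -D * df / h
        # zero flux through faces touching solid cells
        both_fluid = (fluid[_sl(nd, a, slice(0, n - 1))]
                      & fluid[_sl(nd, a, slice(1, n))])
        flux[_sl(nd, a, slice(1, n))] = np.where(both_fluid, adv + diff, 0.0)

        # --- boundary faces
        for side, fi, ci in (("low", 0, 0), ("high", n, n - 1)):
            ub = u[_sl(nd, a, fi)]
            fcell = f[_sl(nd, a, ci)]
            cell_fluid = fluid[_sl(nd, a, ci)]
            bflux = np.zeros(ub.shape)
            handled = np.zeros(ub.shape, dtype=bool)
            for p in grid.patches:
                if p.axis != a or p.side != side:
                    continue
                m = p.face_mask(grid)
                if p.kind == "inflow":
                    cin = inlet_values.get(p.name, 0.0)
                    cin = np.broadcast_to(np.asarray(cin, dtype=float), ub.shape)
                    # advective inflow at the prescribed concentration
                    bflux = np.where(m, ub * cin, bflux)
                else:  # pressure/outflow: zero-gradient
                    bflux = np.where(m, ub * fcell, bflux)
                handled |= m
            # unhandled boundary faces are walls: zero flux
            bflux = np.where(handled & cell_fluid, bflux, 0.0)
            flux[_sl(nd, a, fi)] = bflux

        flux *= Wf
        dfdt -= (flux[_sl(nd, a, slice(1, n + 1))]
                 - flux[_sl(nd, a, slice(0, n))]) / h

    out = f + dt * dfdt
    out[~fluid] = 0.0
    return out


# ------------------------------------------------------------------ stepping


@dataclass
class TransportWorkspace:
    """Per-run scratch state: cached shear-dependent rates and clamp diagnostics."""

    rates: RateTable | None = None
    gamma_dot: np.ndarray | None = None
    clamped_mass: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def update_rates(self, params: KineticParams, gamma_dot):
        self.gamma_dot = np.asarray(gamma_dot)
        self.rates = evaluate_rate_table(params, self.gamma_dot)


def step_species(
    fields: PlateletFields,
    velocity,
    params: KineticParams,
    adhesion_indicator,
    dt: float,
    grid: Grid,
    gamma_dot,
    inlet_profiles: dict | None = None,
    eta_pseudo_dt: float | None = None,
    workspace: TransportWorkspace | None = None,
    n_reaction_substeps: int = 2,
) -> PlateletFields:
    """One fractional step: transport, virtual-substance rebuild, RK4 reactions.

    1. Transport the mobile species and ADP (bound species are immobile).
    2. Rebuild the bound fractions and the virtual substances eta_U, eta_A by a
       single implicit diffusion solve over one platelet diameter.
    3. Integrate the reaction network pointwise with RK4 using
       ``n_reaction_substeps`` sub-steps (default: half the transport step).
    Negative densities produced by limiter undershoot are clamped to zero and
    logged in the workspace.
    """
    ws = workspace or TransportWorkspace()
    if ws.rates is None or ws.gamma_dot is not gamma_dot:
        ws.update_rates(params, gamma_dot)
    inlet_profiles = inlet_profiles or {}

    theta_T = fields.theta_T
    new = fields.copy()
    # 1) transport
    for name in MOBILE_SPECIES:
        inlet_vals = {pname: prof.get(name, 0.0)
                      for pname, prof in inlet_profiles.items()}
        setattr(new, name, advect_diffuse_species(
            getattr(fields, name), velocity, params.D_P, theta_T, dt, grid,
            inlet_values=inlet_vals))
    inlet_adp = {pname: prof.get("ADP", 0.0)
                 for pname, prof in inlet_profiles.items()}
    new.ADP = advect_diffuse_species(
        fields.ADP, velocity, params.D_ADP, theta_T, dt, grid,
        inlet_values=inlet_adp)

    # 2) virtual substances
    if eta_pseudo_dt is None:
        # diffusion length of one platelet diameter (see methods note)
        eta_pseudo_dt = (3.0e-3) ** 2 / params.D_eta
    eta_U = virtual_substance(new.theta_U, params.D_eta, eta_pseudo_dt, grid)
    eta_A = virtual_substance(new.theta_A, params.D_eta, eta_pseudo_dt, grid)

    # 3) reactions (RK4, sub-steps of dt / n)
    _integrate_reactions(new, ws, eta_U, eta_A, adhesion_indicator, params,
                         dt, n_reaction_substeps, grid)
    return new


_REACT_FIELDS = SPECIES + ("ADP", "adp_reservoir")


def _active_cells(fields: PlateletFields, eta_U, eta_A, H_adh, params, grid):
    """Cells where any reaction flux can be nonzero.

    Outside this set every flux vanishes identically: adhesion needs H_adh,
    cohesion needs a virtual substance above the binding threshold eta_t,
    the remaining transitions need bound platelets, ADP or reservoir charge.
    """
    act = (np.asarray(H_adh) > 0)
    act = act | (fields.theta_B > 0) | (fields.ADP > 1e-12)
    act = act | (fields.adp_reservoir > 0)
    act = act | (np.asarray(eta_U) > params.eta_t) | (np.asarray(eta_A) > params.eta_t)
    return act & grid.fluid


def _integrate_reactions(fields: PlateletFields, ws: TransportWorkspace,
                         eta_U, eta_A, H_adh, params, dt, nsub, grid):
    act = _active_cells(fields, eta_U, eta_A, H_adh, params, grid)
    if not np.any(act):
        return
    # gather the active subset into flat vectors
    sub_fields = PlateletFields(
        *(getattr(fields, n)[act] for n in SPECIES),
        fields.ADP[act], fields.adp_reservoir[act], fields.P_max)
    eU = np.asarray(eta_U)[act]
    eA = np.asarray(eta_A)[act]
    H = np.asarray(H_adh)[act]
    gam = ws.gamma_dot[act] if ws.gamma_dot.shape == act.shape else ws.gamma_dot
    rates = ws.rates
    if rates is not None and rates.k_adh_on.shape == act.shape:
        from .kinetics import RateTable
        rates = RateTable(*(getattr(rates, f)[act] for f in
                            ("k_adh_on", "k_adh_off", "k_coh_on", "k_coh_off",
                             "k_act_vwf")))

    sub = dt / nsub
    for _ in range(nsub):
        y0 = {n: getattr(sub_fields, n) for n in _REACT_FIELDS}
        k1 = _rhs(sub_fields, gam, rates, eU, eA, H, params)
        k2 = _rhs_at(sub_fields, y0, k1, sub / 2, gam, rates, eU, eA, H, params)
        k3 = _rhs_at(sub_fields, y0, k2, sub / 2, gam, rates, eU, eA, H, params)
        k4 = _rhs_at(sub_fields, y0, k3, sub, gam, rates, eU, eA, H, params)
        for n in _REACT_FIELDS:
            val = y0[n] + sub / 6.0 * (k1[n] + 2 * k2[n] + 2 * k3[n] + k4[n])
            neg = val < 0
            if np.any(neg):
                ws.clamped_mass += float(-val[neg].sum()) * grid.cell_volume
                val = np.maximum(val, 0.0)
            setattr(sub_fields, n, val)
    # scatter back
    for n in _REACT_FIELDS:
        full = getattr(fields, n)
        full[act] = getattr(sub_fields, n)


def _rhs(fields, gam, rates, eta_U, eta_A, H_adh, params):
    return reaction_rhs(fields, gam, eta_U, eta_A, H_adh, params,
                        rates=rates, validate=False)


def _rhs_at(fields, y0, k, h, gam, rates, eta_U, eta_A, H_adh, params):
    trial = PlateletFields(
        *(np.maximum(y0[n] + h * k[n], 0.0) for n in SPECIES),
        np.maximum(y0["ADP"] + h * k["ADP"], 0.0),
        np.maximum(y0["adp_reservoir"] + h * k["adp_reservoir"], 0.0),
        fields.P_max)
    return _rhs(trial, gam, rates, eta_U, eta_A, H_adh, params)
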