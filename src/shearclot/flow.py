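"""Incompressible Stokes/Navier–Stokes–Brinkman flow on the staggered grid.

The growing platelet aggregate enters the momentum balance as a volumetric
Brinkman drag -mu * alpha(theta_B) * u with a Carman–Kozeny resistance
alpha(theta_B) = C_CK (0.6 theta_B)^2 / (1 - 0.6 theta_B)^3.

Two solution modes are provided:

* :meth:`FlowSolver.solve_steady` — the quasi-static mode: a coupled sparse
  solve of the steady Stokes–Brinkman system (inertia neglected; Re << 1 in
  every scenario here).  Clot growth is slow relative to viscous relaxation,
  so scenario runs re-solve this system periodically as alpha evolves.
* :meth:`step_fluid` — the transient reference: one implicit time step of the
  Navier–Stokes–Brinkman equations (explicit upwind advection; viscous,
  Brinkman and pressure treated implicitly in a single coupled solve, which
  enforces the divergence constraint to solver precision).

Unit system: mm, s, mg.  Viscosity mu is then numerically Pa*s * 1e3
(blood: mu = 3.5 mg/(mm s) = 3.5e-3 Pa*s) and pressure is in mPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import FLUID, Grid

__all__ = [
    "FluidState",
    "ResistanceParams",
    "carman_kozeny_resistance",
    "FlowSolver",
    "step_fluid",
    "shear_rate_field",
    "flow_rate_through_plane",
    "channel_inflow_profile",
]

# face types
_MOM = 0   # interior momentum equation
_DIR = 1   # Dirichlet velocity (no-slip wall, inflow, solid-adjacent)
_PB = 2    # boundary face with prescribed pressure (open boundary)

MM3_PER_S_TO_UL_PER_MIN = 60.0  # 1 mm^3 = 1 uL


@dataclass
class ResistanceParams:
    """Carman–Kozeny coefficient C_CK (mm^-2)."""

    C_CK: float = 1.0e6

    def __post_init__(self):
        if self.C_CK < 0:
            raise ValueError("C_CK must be nonnegative")


def carman_kozeny_resistance(theta_B, params: ResistanceParams | None = None):
    """Brinkman resistance alpha(theta_B) (mm^-2), monotone in the bound fraction."""
    if params is None:
        params = ResistanceParams()
    t = np.asarray(theta_B, dtype=float)
    if np.any(0.6 * t >= 1.0):
        raise ValueError("nonphysical packing: 0.6*theta_B must stay below 1")
    phi = 0.6 * t
    out = params.C_CK * phi**2 / (1.0 - phi) ** 3
    return out if out.ndim else float(out)


@dataclass
class FluidState:
    """Face-normal velocities (mm/s) and cell-centered pressure (mPa)."""

    velocity: tuple  # one array per axis; axis-a component has dims[a]+1 entries along a
    pressure: np.ndarray
    rho: float = 1.06   # mg/mm^3
    mu: float = 3.5     # mg/(mm s)  (= 3.5e-3 Pa s)

    @classmethod
    def zeros(cls, grid: Grid, rho: float = 1.06, mu: float = 3.5) -> "FluidState":
        vel = tuple(
            np.zeros(_face_shape(grid, a), dtype=np.float64)
            for a in range(grid.ndim)
        )
        return cls(vel, np.zeros(grid.dims, dtype=np.float64), rho, mu)

    def copy(self) -> "FluidState":
        return FluidState(tuple(v.copy() for v in self.velocity),
                          self.pressure.copy(), self.rho, self.mu)

    def max_speed(self) -> float:
        return max(float(np.abs(v).max()) for v in self.velocity)


def _face_shape(grid: Grid, axis: int) -> tuple:
    s = list(grid.dims)
    s[axis] += 1
    return tuple(s)


def _sl(ndim, axis, s):
    out = [slice(None)] * ndim
    out[axis] = s
    return tuple(out)


class FlowSolver:
    """Assembles and solves the coupled Stokes–Brinkman system on a Grid.

    Face classification, the unknown numbering, and the boundary ghost rules
    are computed once per grid; only the Brinkman field and boundary values
    change between solves.
    """

    def __init__(self, grid: Grid, rho: float = 1.06, mu: float = 3.5,
                 div_tol: float = 1e-8):
        self.grid = grid
        self.rho = rho
        self.mu = mu
        self.div_tol = div_tol
        nd = grid.ndim
        self._face_idx = []
        offset = 0
        for a in range(nd):
            shape = _face_shape(grid, a)
            self._face_idx.append(np.arange(offset, offset + int(np.prod(shape)),
                                            dtype=np.int64).reshape(shape))
            offset += int(np.prod(shape))
        self._p_off = offset
        self._p_idx = np.arange(offset, offset + int(np.prod(grid.dims)),
                                dtype=np.int64).reshape(grid.dims)
        self.n_unknowns = offset + int(np.prod(grid.dims))
        self._classify()

    # ------------------------------------------------------------------ setup
    def _boundary_patch_info(self, axis, side):
        """(kind_map, value_map) over the boundary plane for axis/side.

        kind: 0 = wall (mirror ghost), 1 = inflow (Dirichlet normal velocity),
        2 = pressure (zero-gradient tangential ghost, prescribed pressure).
        """
        g = self.grid
        shape = tuple(n for a, n in enumerate(g.dims) if a != axis)
        kind = np.zeros(shape, dtype=np.int8)
        val = np.zeros(shape, dtype=np.float64)
        for p in g.patches:
            if p.axis != axis or p.side != side:
                continue
            m = p.face_mask(g)
            if p.kind == "inflow":
                kind[m] = 1
            elif p.kind in ("pressure", "outflow"):
                kind[m] = 2
                val[m] = p.value
        return kind, val

    def _classify(self):
        g = self.grid
        nd = g.ndim
        fluid = g.fluid
        self._ftype = []
        self._bkind = {}  # (axis, side) -> kind map over boundary plane
        self._bval = {}
        for a in range(nd):
            for side in ("low", "high"):
                k, v = self._boundary_patch_info(a, side)
                self._bkind[(a, side)] = k
                self._bval[(a, side)] = v
        for a in range(nd):
            shape = _face_shape(g, a)
            ft = np.full(shape, _DIR, dtype=np.int8)
            n = g.dims[a]
            # interior faces: momentum where both neighbors are fluid
            lo = fluid[_sl(nd, a, slice(0, n - 1))]
            hi = fluid[_sl(nd, a, slice(1, n))]
            ft[_sl(nd, a, slice(1, n))] = np.where(lo & hi, _MOM, _DIR)
            # boundary faces
            for side, fi, ci in (("low", 0, 0), ("high", n, n - 1)):
                kind = self._bkind[(a, side)]
                cell_fluid = fluid[_sl(nd, a, ci)]
                face = ft[_sl(nd, a, fi)]
                face[...] = np.where((kind == 2) & cell_fluid, _PB, _DIR)
            self._ftype.append(ft)

    # ------------------------------------------------------------- assembly
    def _face_alpha(self, alpha, axis):
        """Brinkman coefficient at faces (average of adjacent cells; solid -> large)."""
        g = self.grid
        a_cell = np.where(g.fluid, alpha, 0.0)
        n = g.dims[axis]
        nd = g.ndim
        out = np.zeros(_face_shape(g, axis))
        lo = a_cell[_sl(nd, axis, slice(0, n - 1))]
        hi = a_cell[_sl(nd, axis, slice(1, n))]
        out[_sl(nd, axis, slice(1, n))] = 0.5 * (lo + hi)
        out[_sl(nd, axis, 0)] = a_cell[_sl(nd, axis, 0)]
        out[_sl(nd, axis, n)] = a_cell[_sl(nd, axis, n - 1)]
        return out

    def assemble(self, alpha, inflow=None, dt=None, state=None):
        """Assemble A x = b for the coupled (u, p) system.

        alpha : cell-centered Brinkman resistance (mm^-2)
        inflow : dict patch_name -> boundary-plane array of the prescribed
            signed normal velocity (mm/s)
        dt, state : when given, adds the implicit Euler time term and the
            explicit advective term evaluated from ``state``.
        """
        g = self.grid
        nd = g.ndim
        mu = self.mu
        rows, cols, vals = [], [], []
        rhs = np.zeros(self.n_unknowns)

        inflow_vals = self._inflow_face_values(inflow)
        adv = None
        if dt is not None and state is not None:
            adv = _advective_term(g, state)

        for a in range(nd):
            ft = self._ftype[a]
            fidx = self._face_idx[a]
            ha = g.spacing[a]
            alpha_f = self._face_alpha(alpha, a)
            mom = ft == _MOM
            pb = ft == _PB
            diag = np.zeros(ft.shape)

            # Laplacian legs
            for b in range(nd):
                hb = g.spacing[b]
                c = mu / hb**2
                nb_max = ft.shape[b] - 1
                for sgn in (-1, 1):
                    pos = np.arange(ft.shape[b]) + sgn
                    in_range = (pos >= 0) & (pos <= nb_max)
                    # momentum faces whose neighbor along b exists
                    m_in = mom & _broadcast_mask(in_range, ft.shape, b)
                    if np.any(m_in):
                        nb_idx = np.roll(fidx, -sgn, axis=b)
                        rows.append(fidx[m_in])
                        cols.append(nb_idx[m_in])
                        vals.append(np.full(int(m_in.sum()), c))
                    m_out = mom & ~_broadcast_mask(in_range, ft.shape, b)
                    if np.any(m_out):
                        # domain-boundary ghost along a tangential axis
                        side = "low" if sgn < 0 else "high"
                        gk = self._ghost_kind(a, b, side, ft.shape)
                        # mirror (wall/inflow): ghost = -u ; zgrad: ghost = +u
                        gcoef = np.where(gk == 2, c, -c)
                        diag[m_out] += gcoef[m_out]
                diag[mom] -= 2 * c
            # Brinkman + time term on the diagonal
            diag[mom] -= mu * alpha_f[mom]
            if dt is not None:
                diag[mom] -= self.rho / dt

            rows.append(fidx[mom])
            cols.append(fidx[mom])
            vals.append(diag[mom])

            # pressure gradient at interior momentum faces
            n = g.dims[a]
            face_interior = np.zeros(ft.shape, dtype=bool)
            face_interior[_sl(nd, a, slice(1, n))] = True
            mi = mom & face_interior
            if np.any(mi):
                pr_i = self._p_idx[_sl(nd, a, slice(1, n))]
                pl_i = self._p_idx[_sl(nd, a, slice(0, n - 1))]
                sel = mi[_sl(nd, a, slice(1, n))]
                r = fidx[_sl(nd, a, slice(1, n))][sel]
                rows.extend([r, r])
                cols.extend([pr_i[sel], pl_i[sel]])
                vals.extend([np.full(r.size, -1.0 / ha),
                             np.full(r.size, 1.0 / ha)])

            # open-boundary (prescribed pressure) faces
            for side, fi, ci in (("low", 0, 0), ("high", n, n - 1)):
                face_sel = _sl(nd, a, fi)
                sel = pb[face_sel]
                if not np.any(sel):
                    continue
                r = fidx[face_sel][sel]
                pcell = self._p_idx[_sl(nd, a, ci)][sel]
                uin_idx = self._face_idx[a][_sl(nd, a, 1 if side == "low" else n - 1)][sel]
                pbv = self._bval[(a, side)][sel]
                c_a = mu / ha**2
                # one-sided Laplacian along a (zero-gradient ghost outside)
                rows.extend([r, r])
                cols.extend([uin_idx, r])
                vals.extend([np.full(r.size, c_a), np.full(r.size, -c_a)])
                dg = -mu * alpha_f[face_sel][sel]
                if dt is not None:
                    dg = dg - self.rho / dt
                rows.append(r)
                cols.append(r)
                vals.append(dg)
                # tangential Laplacian legs
                for b in range(nd):
                    if b == a:
                        continue
                    hb = g.spacing[b]
                    cb = mu / hb**2
                    for sgn in (-1, 1):
                        nb = np.roll(fidx, -sgn, axis=b)[face_sel][sel]
                        posb = _index_along(ft.shape, b)[face_sel][sel] + sgn
                        ok = (posb >= 0) & (posb <= ft.shape[b] - 1)
                        rows.append(r[ok])
                        cols.append(nb[ok])
                        vals.append(np.full(int(ok.sum()), cb))
                        # out-of-range tangential ghost: mirror
                        rows.append(r[~ok])
                        cols.append(r[~ok])
                        vals.append(np.full(int((~ok).sum()), -cb))
                    rows.append(r)
                    cols.append(r)
                    vals.append(np.full(r.size, -2 * cb))
                # pressure: gradient over half cell to the prescribed value
                sign = 1.0 if side == "low" else -1.0
                rows.append(r)
                cols.append(pcell)
                vals.append(np.full(r.size, -sign * 2.0 / ha))
                rhs[r] += -sign * 2.0 / ha * pbv

            # Dirichlet faces
            dirm = ft == _DIR
            r = fidx[dirm]
            rows.append(r)
            cols.append(r)
            vals.append(np.ones(r.size))
            rhs[r] = inflow_vals[a][dirm]

            # transient explicit terms on momentum + PB rows
            if dt is not None and state is not None:
                act = mom | pb
                r = fidx[act]
                rhs[r] += (-self.rho / dt * state.velocity[a][act]
                           + self.rho * adv[a][act])

        # continuity rows
        fluid = self.grid.fluid
        for a in range(nd):
            ha = g.spacing[a]
            hi = self._face_idx[a][_sl(nd, a, slice(1, g.dims[a] + 1))]
            lo = self._face_idx[a][_sl(nd, a, slice(0, g.dims[a]))]
            r = self._p_idx[fluid]
            rows.extend([r, r])
            cols.extend([hi[fluid], lo[fluid]])
            vals.extend([np.full(r.size, 1.0 / ha), np.full(r.size, -1.0 / ha)])
        # solid cells: pin pressure
        r = self._p_idx[~fluid]
        rows.append(r)
        cols.append(r)
        vals.append(np.ones(r.size))
        # closed domain: pin one pressure
        if not any(p.kind in ("pressure", "outflow") for p in g.patches):
            cell = self._p_idx[fluid][0]
            # overwrite that continuity row by p = 0
            rows.append(np.array([cell]))
            cols.append(np.array([cell]))
            vals.append(np.array([1.0]))
            self._pinned = cell
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        A = sp.coo_matrix((vals, (rows, cols)),
                          shape=(self.n_unknowns, self.n_unknowns)).tocsr()
        return A, rhs

    def _ghost_kind(self, a, b, side, shape):
        """Boundary kind along tangential axis b for u_a faces (broadcast array).

        kind_plane lives on the boundary-plane cells (all axes except b);
        clamp-index it onto the face shape (faces have dims[a]+1 entries
        along a).
        """
        g = self.grid
        kind_plane = self._bkind[(b, side)]
        plane_axes = [ax for ax in range(g.ndim) if ax != b]
        idxs = tuple(np.minimum(_index_along(shape, ax), g.dims[ax] - 1)
                     for ax in plane_axes)
        return kind_plane[idxs]

    def _inflow_face_values(self, inflow):
        """Dirichlet values on each face array (inflow profiles; walls are 0)."""
        g = self.grid
        nd = g.ndim
        vals = [np.zeros(_face_shape(g, a)) for a in range(nd)]
        if not inflow:
            return vals
        for name, profile in inflow.items():
            p = g.patch_by_name(name)
            fi = 0 if p.side == "low" else g.dims[p.axis]
            mask = p.face_mask(g)
            target = vals[p.axis][_sl(nd, p.axis, fi)]
            target[mask] = np.asarray(profile)[mask]
        return vals

    # --------------------------------------------------------------- solving
    def solve_steady(self, alpha, inflow=None) -> FluidState:
        """Solve the steady Stokes–Brinkman system; divergence-free to solver precision."""
        A, b = self.assemble(alpha, inflow=inflow)
        x = spla.spsolve(A.tocsc(), b)
        if not np.all(np.isfinite(x)):
            raise RuntimeError("steady Stokes-Brinkman solve failed (singular system)")
        return self._unpack(x)

    def step(self, state: FluidState, alpha, dt, inflow=None,
             cfl_limit: float = 1.0) -> FluidState:
        """One implicit transient step (explicit advection; see module docstring)."""
        umax = state.max_speed()
        if umax > 0:
            cfl = umax * dt / min(self.grid.spacing)
            if cfl > cfl_limit:
                raise ValueError(
                    f"advective CFL {cfl:.2f} exceeds {cfl_limit} (dt={dt:g})")
        A, b = self.assemble(alpha, inflow=inflow, dt=dt, state=state)
        x = spla.spsolve(A.tocsc(), b)
        if not np.all(np.isfinite(x)):
            raise RuntimeError("transient flow solve failed")
        new = self._unpack(x)
        return new

    def _unpack(self, x) -> FluidState:
        g = self.grid
        vel = []
        for a in range(g.ndim):
            shape = _face_shape(g, a)
            n = int(np.prod(shape))
            off = int(self._face_idx[a].flat[0])
            vel.append(x[off:off + n].reshape(shape))
        p = x[self._p_off:].reshape(g.dims)
        return FluidState(tuple(vel), p, self.rho, self.mu)

    def divergence(self, state: FluidState) -> np.ndarray:
        g = self.grid
        nd = g.ndim
        div = np.zeros(g.dims)
        for a in range(nd):
            hi = state.velocity[a][_sl(nd, a, slice(1, g.dims[a] + 1))]
            lo = state.velocity[a][_sl(nd, a, slice(0, g.dims[a]))]
            div += (hi - lo) / g.spacing[a]
        div[~g.fluid] = 0.0
        return div


def _index_along(shape, axis):
    ii = np.arange(shape[axis])
    sh = [1] * len(shape)
    sh[axis] = -1
    return np.broadcast_to(ii.reshape(sh), shape)


def _broadcast_mask(mask1d, shape, axis):
    sh = [1] * len(shape)
    sh[axis] = -1
    return np.broadcast_to(mask1d.reshape(sh), shape)


def step_fluid(state: FluidState, grid: Grid, alpha, dt, inflow=None,
               solver: FlowSolver | None = None) -> FluidState:
    """Advance the flow one implicit timestep (convenience wrapper)."""
    if solver is None:
        solver = FlowSolver(grid, rho=state.rho, mu=state.mu)
    return solver.step(state, alpha, dt, inflow=inflow)


def _advective_term(grid: Grid, state: FluidState):
    """First-order upwind (u . grad) u_a evaluated at the u_a faces."""
    nd = grid.ndim
    out = []
    for a in range(nd):
        ua = state.velocity[a]
        adv = np.zeros_like(ua)
        for b in range(nd):
            hb = grid.spacing[b]
            if b == a:
                ub_here = ua
            else:
                ub_here = _interp_to_faces(grid, state.velocity[b], b, a)
            fwd = (np.roll(ua, -1, axis=b) - ua) / hb
            bwd = (ua - np.roll(ua, 1, axis=b)) / hb
            # kill wrapped differences at the ends
            fwd[_sl(nd, b, -1)] = 0.0
            bwd[_sl(nd, b, 0)] = 0.0
            adv += np.where(ub_here > 0, ub_here * bwd, ub_here * fwd)
        out.append(adv)
    return out


def _interp_to_faces(grid: Grid, ub, b, a):
    """Interpolate component b (on b-faces) to the a-face locations."""
    nd = grid.ndim
    # average along b to cell centers
    nb = grid.dims[b]
    cc = 0.5 * (ub[_sl(nd, b, slice(0, nb))] + ub[_sl(nd, b, slice(1, nb + 1))])
    # average along a to a-faces (pad with edge values)
    na = grid.dims[a]
    out_shape = _face_shape(grid, a)
    out = np.zeros(out_shape)
    out[_sl(nd, a, slice(1, na))] = 0.5 * (
        cc[_sl(nd, a, slice(0, na - 1))] + cc[_sl(nd, a, slice(1, na))])
    out[_sl(nd, a, 0)] = cc[_sl(nd, a, 0)]
    out[_sl(nd, a, na)] = cc[_sl(nd, a, na - 1)]
    return out


def cell_center_velocity(grid: Grid, state: FluidState) -> list:
    """Velocity components interpolated to cell centers (zero in solid cells)."""
    nd = grid.ndim
    out = []
    for a in range(nd):
        n = grid.dims[a]
        v = 0.5 * (state.velocity[a][_sl(nd, a, slice(0, n))]
                   + state.velocity[a][_sl(nd, a, slice(1, n + 1))])
        v = np.where(grid.fluid, v, 0.0)
        out.append(v)
    return out


def shear_rate_field(state: FluidState, grid: Grid) -> np.ndarray:
    """Local shear rate sqrt(2 D:D) (1/s) at cell centers.

    D is the symmetric part of the velocity gradient.  Wall-normal derivatives
    next to no-slip boundaries use a mirrored ghost (u_ghost = -u) so that the
    wall shear of a resolved Poiseuille profile is recovered to discretization
    error.
    """
    nd = grid.ndim
    ucc = cell_center_velocity(grid, state)
    gradu = [[None] * nd for _ in range(nd)]
    for a in range(nd):
        n = grid.dims[a]
        # exact staggered derivative d u_a / d x_a
        gradu[a][a] = (state.velocity[a][_sl(nd, a, slice(1, n + 1))]
                       - state.velocity[a][_sl(nd, a, slice(0, n))]) / grid.spacing[a]
        for b in range(nd):
            if b == a:
                continue
            gradu[a][b] = _cc_derivative(grid, ucc[a], b)
    D2 = np.zeros(grid.dims)
    for a in range(nd):
        for b in range(nd):
            Dab = 0.5 * (gradu[a][b] + gradu[b][a])
            D2 += Dab * Dab
    out = np.sqrt(2.0 * D2)
    out[~grid.fluid] = 0.0
    return out


def _cc_derivative(grid: Grid, f, axis):
    """Central derivative of a cell-centered field with no-slip mirror ghosts."""
    nd = grid.ndim
    h = grid.spacing[axis]
    n = grid.dims[axis]
    pad_lo = -f[_sl(nd, axis, slice(0, 1))]
    pad_hi = -f[_sl(nd, axis, slice(n - 1, n))]
    # open (inflow/outflow/pressure) boundaries: zero-gradient ghost instead
    for p in grid.patches:
        if p.axis != axis:
            continue
        if p.side == "low":
            pad_lo = f[_sl(nd, axis, slice(0, 1))]
        else:
            pad_hi = f[_sl(nd, axis, slice(n - 1, n))]
    fp = np.concatenate([pad_lo, f, pad_hi], axis=axis)
    hi = fp[_sl(nd, axis, slice(2, n + 2))]
    lo = fp[_sl(nd, axis, slice(0, n))]
    return (hi - lo) / (2 * h)


def flow_rate_through_plane(state: FluidState, grid: Grid, axis: int,
                            position_mm: float, region=None) -> float:
    """Volumetric flow through a grid cross-section, in uL/min.

    ``position_mm`` selects the nearest face plane normal to ``axis``;
    ``region`` optionally restricts the plane to a cell mask (boolean array of
    grid.dims collapsed along axis, or full dims array).
    """
    nd = grid.ndim
    i = int(round((position_mm - grid.origin[axis]) / grid.spacing[axis]))
    i = min(max(i, 0), grid.dims[axis])
    u = state.velocity[axis][_sl(nd, axis, i)]
    ci = min(i, grid.dims[axis] - 1)
    fluid_plane = grid.fluid[_sl(nd, axis, ci)]
    if region is not None:
        region = np.asarray(region)
        if region.ndim == nd:
            region = region[_sl(nd, axis, ci)]
        fluid_plane = fluid_plane & region
    if not np.any(fluid_plane):
        raise ValueError("cross-section plane intersects solid-only cells")
    q = float(np.sum(u[fluid_plane])) * grid.face_area(axis)  # mm^3/s
    return q * MM3_PER_S_TO_UL_PER_MIN


def channel_inflow_profile(grid: Grid, wall_shear: float,
                           patch_name: str = "inlet") -> np.ndarray:
    """Inflow normal-velocity profile giving a target wall shear rate (1/s).

    Parabolic in the wall-normal (last) axis; in 3D additionally parabolic in
    the width axis.  The amplitude is chosen so the analytic wall shear of the
    wall-normal parabola at the reactive wall equals ``wall_shear``.
    """
    patch = grid.patch_by_name(patch_name)
    axis = patch.axis
    plane_axes = [a for a in range(grid.ndim) if a != axis]
    h_axis = plane_axes[-1]  # wall-normal (height) axis
    h = grid.extents[h_axis]
    umax = wall_shear * h / 4.0
    shape = tuple(grid.dims[a] for a in plane_axes)
    prof = np.ones(shape)
    coords = [grid.cell_centers(a) - grid.origin[a] for a in plane_axes]
    # parabola in the height axis
    yh = coords[-1]
    para_h = 4.0 * yh * (h - yh) / h**2
    sh = [1] * len(shape)
    sh[-1] = -1
    prof = prof * para_h.reshape(sh)
    if len(plane_axes) == 2:
        w = grid.extents[plane_axes[0]]
        yw = coords[0]
        para_w = 4.0 * yw * (w - yw) / w**2
        prof = prof * para_w.reshape((-1, 1))
    sign = 1.0 if patch.side == "low" else -1.0
    return sign * umax * prof
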