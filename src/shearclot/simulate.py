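"""Scenario orchestration: grid build, inlet build, time loop, metrics, outputs.

The time loop couples the flow and species quasi-statically: the steady
Stokes–Brinkman system is re-solved at a configurable simulated-time interval
(clot growth is slow relative to viscous relaxation, which is sub-millisecond
at these scales), and the species advance between flow updates with the
CFL-limited transport step.  A fully transient flow mode
(:func:`shearclot.flow.step_fluid`) is available for reference studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import RunConfig, kinetics_from_config, save_config
from .flow import (
    FlowSolver,
    FluidState,
    ResistanceParams,
    carman_kozeny_resistance,
    channel_inflow_profile,
    flow_rate_through_plane,
    shear_rate_field,
)
from .grid import AdhesionRegion, Grid, build_bleeding_chip_grid, build_channel_grid, generate_adhesion_region
from .inlet import marginated_profile
from .io import write_series_csv, write_summary_json, write_vtk
from .kinetics import PlateletFields, default_params
from .metrics import (
    ClotTimeSeries,
    OcclusionCriterion,
    aggregate_volume,
    clot_height,
    core_shell_fractions,
    occlusion_time,
)
from .transport import TransportWorkspace, step_species

log = logging.getLogger("shearclot")

__all__ = ["RunResult", "run_simulation", "build_scenario",
           "chip_injury_adhesion", "duct_inflow_profile"]


@dataclass
class RunResult:
    config: RunConfig
    grid: Grid
    series: ClotTimeSeries
    fields: PlateletFields
    flow: FluidState
    occlusion: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    output_dir: Path | None = None


def duct_inflow_profile(grid: Grid, patch_name: str, mean_velocity: float):
    """Parabolic normal-velocity profile over a duct inflow patch (2D/3D).

    The parabola spans the patch extent in the width axis (and the full height
    in 3D), normalized so the patch-average equals ``mean_velocity``.
    """
    patch = grid.patch_by_name(patch_name)
    plane_axes = [a for a in range(grid.ndim) if a != patch.axis]
    shape = tuple(grid.dims[a] for a in plane_axes)
    prof = np.ones(shape)
    mask = patch.face_mask(grid)
    if patch.extent is not None:
        for k, (a, (lo, hi)) in enumerate(zip(plane_axes, patch.extent)):
            c = grid.cell_centers(a)
            para = np.clip(4 * (c - lo) * (hi - c) / (hi - lo) ** 2, 0.0, None)
            sh = [1] * len(shape)
            sh[k] = -1
            prof = prof * para.reshape(sh)
    else:
        for k, a in enumerate(plane_axes):
            lo = grid.origin[a]
            hi = lo + grid.extents[a]
            c = grid.cell_centers(a)
            para = 4 * (c - lo) * (hi - c) / (hi - lo) ** 2
            sh = [1] * len(shape)
            sh[k] = -1
            prof = prof * para.reshape(sh)
    prof = np.where(mask, prof, 0.0)
    m = prof[mask].mean() if np.any(mask) else 1.0
    sign = 1.0 if patch.side == "low" else -1.0
    return sign * mean_velocity / m * prof


def chip_injury_adhesion(grid: Grid, platelet_diameter: float,
                         site_fraction: float = 1.0, seed: int = 0) -> AdhesionRegion:
    """Adhesion indicator on the injury-channel walls of a bleeding chip.

    Eligible cells are fluid cells inside the injury-channel box whose center
    lies within one platelet diameter of a solid wall (the first cell layer
    against the wall is always eligible).  A seeded permutation selects a
    ``site_fraction`` subset.
    """
    (x0, x1), (y0, y1) = grid.injury_box
    xs = grid.cell_centers(0)
    ys = grid.cell_centers(1)
    inbox = np.ones(grid.dims, dtype=bool)
    inbox &= ((xs >= x0 - 1e-12) & (xs <= x1 + 1e-12)).reshape(
        (-1,) + (1,) * (grid.ndim - 1))
    sh = [1] * grid.ndim
    sh[1] = -1
    inbox &= ((ys >= y0 - 1e-12) & (ys <= y1 + 1e-12)).reshape(sh)
    # distance to the nearest solid cell (in mm), via EDT on the fluid mask
    dist = ndimage.distance_transform_edt(grid.fluid, sampling=grid.spacing)
    eligible = grid.fluid & inbox & (
        (dist <= platelet_diameter + 1e-12) | (dist <= min(grid.spacing) + 1e-12))
    indicator = np.zeros(grid.dims)
    cells = np.argwhere(eligible)
    if site_fraction >= 1.0:
        indicator[eligible] = 1.0
    elif len(cells):
        rng = np.random.default_rng(seed)
        k = int(round(site_fraction * len(cells)))
        sel = rng.permutation(len(cells))[:k]
        for c in cells[sel]:
            indicator[tuple(c)] = 1.0
    return AdhesionRegion(indicator, ((x0, x1), (y0, y1)), platelet_diameter,
                          site_fraction, seed)


def build_scenario(cfg: RunConfig):
    """Build (grid, adhesion, inflow velocity profiles, inlet species profiles)."""
    geo = cfg.geometry
    kind = geo.get("kind", "channel")
    if kind == "channel":
        grid = build_channel_grid(geo["length"], geo["width"],
                                  geo.get("height"), geo["spacing"],
                                  mode_2d=geo.get("mode_2d", False))
        wall_shear = cfg.fluid.get("wall_shear", 300.0)
        vel_prof = {"inlet": channel_inflow_profile(grid, wall_shear)}
        patch_extent = cfg.adhesion.get("patch_extent")
        if patch_extent is None:
            L = grid.extents[0]
            patch_extent = [[L * 0.2, L * 0.8]]
            if grid.ndim == 3:
                W = grid.extents[1]
                patch_extent.append([W * 0.2, W * 0.8])
        adhesion = generate_adhesion_region(
            grid, tuple(tuple(e) for e in patch_extent),
            cfg.adhesion.get("platelet_diameter", 0.003),
            cfg.adhesion.get("site_fraction", 1.0), cfg.seed)
        inlet_names = ["inlet"]
    elif kind == "chip":
        grid = build_bleeding_chip_grid(
            tuple(geo["blood_channel"]), tuple(geo["wash_channel"]),
            tuple(geo["injury_channel"]), geo["spacing"],
            mode_2d=geo.get("mode_2d", True),
            junction_frac=geo.get("junction_frac", 0.5))
        vel_prof = {
            "blood_in": duct_inflow_profile(
                grid, "blood_in", cfg.fluid.get("blood_mean_velocity", 10.0)),
            "wash_in": duct_inflow_profile(
                grid, "wash_in", cfg.fluid.get("wash_mean_velocity", 20.0)),
        }
        adhesion = chip_injury_adhesion(
            grid, cfg.adhesion.get("platelet_diameter", 0.003),
            cfg.adhesion.get("site_fraction", 1.0), cfg.seed)
        inlet_names = ["blood_in"]
    else:
        raise ValueError(f"unknown geometry kind {kind!r}")

    mean_count = cfg.inlet.get("mean_count", 2.5e5)
    species_prof = {}
    for name in inlet_names:
        species_prof[name] = marginated_profile(
            grid, mean_count, cfg.inlet.get("enhancement", 2.5),
            cfg.inlet.get("layer_thickness", 0.003), patch_name=name)
    return grid, adhesion, vel_prof, species_prof


def _initial_fields(grid: Grid, cfg: RunConfig, params) -> PlateletFields:
    fields = PlateletFields.zeros(grid.dims, params.P_max)
    mean_count = cfg.inlet.get("mean_count", 2.5e5)
    if cfg.geometry.get("kind", "channel") == "chip":
        # blood initially fills the blood channel and the injury channel
        (_, _), (y0, y1) = grid.injury_box
        ys = grid.cell_centers(1)
        sh = [1] * grid.ndim
        sh[1] = -1
        blood_side = np.broadcast_to((ys >= y0).reshape(sh), grid.dims)
        fields.P_mu[grid.fluid & blood_side] = mean_count
    else:
        fields.P_mu[grid.fluid] = mean_count
    return fields


def _injury_flow(grid: Grid, state: FluidState, cfg: RunConfig) -> float:
    if cfg.geometry.get("kind") == "chip":
        (x0, x1), (y0, y1) = grid.injury_box
        xs = grid.cell_centers(0)
        region = np.zeros(grid.dims, dtype=bool)
        sel = (xs >= x0 - 1e-12) & (xs <= x1 + 1e-12)
        region[sel] = True
        # magnitude of the flow leaving the injury channel at its wash end
        return abs(flow_rate_through_plane(state, grid, 1, y0, region=region))
    # straight channel: outlet flow
    return abs(flow_rate_through_plane(state, grid, 0, grid.extents[0]))


def run_simulation(cfg: RunConfig) -> RunResult:
    """Execute a configured scenario end to end; deterministic for fixed seed."""
    params = kinetics_from_config(cfg.kinetics) if cfg.kinetics else default_params()
    grid, adhesion, vel_prof, species_prof = build_scenario(cfg)
    rho = cfg.fluid.get("rho", 1.06)
    mu = cfg.fluid.get("mu", 3.5)
    ck = ResistanceParams(cfg.fluid.get("C_CK", 1.0e6))
    solver = FlowSolver(grid, rho=rho, mu=mu)
    fields = _initial_fields(grid, cfg, params)
    ws = TransportWorkspace()

    inlet_profiles = {name: prof.species_profiles
                      for name, prof in species_prof.items()}

    t_end = float(cfg.simulation.get("t_end", 10.0))
    adp_on = bool(cfg.simulation.get("adp_on", True))
    stop_on_occ = bool(cfg.simulation.get("stop_on_occlusion", False))
    if not adp_on:
        from dataclasses import replace as _rep
        params = _rep(params, adp_act_rate=0.0, adp_release_total=0.0)

    # exact wall-shear targeting: Stokes flow is linear in the boundary data,
    # so one clean-channel solve fixes the inflow amplitude that puts the
    # wall-adjacent-cell shear at the requested value over the patch center.
    if cfg.geometry.get("kind", "channel") == "channel" and \
            cfg.fluid.get("wall_shear"):
        st0 = solver.solve_steady(np.zeros(grid.dims), inflow=vel_prof)
        gam0 = shear_rate_field(st0, grid)
        idx = [n // 2 for n in grid.dims]
        idx[-1] = 0  # first cell above the reactive wall
        measured = float(gam0[tuple(idx)])
        if measured > 0:
            scale = float(cfg.fluid["wall_shear"]) / measured
            vel_prof = {k: v * scale for k, v in vel_prof.items()}

    cfl = float(cfg.transport.get("cfl_safety", 0.5))
    flow_every = float(cfg.transport.get("flow_update_interval", 0.05))
    eta_len = cfg.transport.get("eta_diffusion_length") or max(
        0.003, 1.0 * min(grid.spacing))
    eta_pseudo_dt = eta_len**2 / params.D_eta
    rec_int = float(cfg.metrics.get("record_interval", 0.25))
    vis_thr = float(cfg.metrics.get("vis_threshold", 0.1))
    occ_cfg = cfg.metrics.get("occlusion", {})
    criterion = OcclusionCriterion(occ_cfg.get("kind", "flow_threshold"),
                                   occ_cfg.get("threshold", 0.35))
    vtk_int = float(cfg.metrics.get("vtk_interval", 0.0))

    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        save_config(cfg, out_dir / "config.yaml")

    series = ClotTimeSeries()
    log_lines = []

    t = 0.0
    next_flow, next_rec, next_vtk = 0.0, 0.0, 0.0
    state = None
    gamma = None
    dt = None
    occluded_at = None
    step_i = 0
    while t < t_end - 1e-12:
        if state is None or t >= next_flow - 1e-12:
            alpha = carman_kozeny_resistance(
                np.minimum(fields.theta_B, 1.2), ck)
            state = solver.solve_steady(alpha, inflow=vel_prof)
            gamma = shear_rate_field(state, grid)
            ws.update_rates(params, gamma)
            umax = state.max_speed()
            hmin = min(grid.spacing)
            dmax = max(params.D_P, params.D_ADP)
            # combined explicit advection + diffusion stability bound
            rate = umax / hmin + 2 * grid.ndim * dmax / hmin**2
            dt = cfl / max(rate, 1e-9)
            dt = min(dt, rec_int)
            next_flow = t + flow_every
        if t >= next_rec - 1e-12:
            theta_B = fields.theta_B
            q = _injury_flow(grid, state, cfg)
            totals = {n: float(getattr(fields, n)[grid.fluid].sum()
                               * grid.cell_volume)
                      for n in ("P_mu", "P_ma", "P_bvu", "P_bva", "P_bfa",
                                "P_seu", "P_sea")}
            series.append(
                t, aggregate_volume(theta_B, vis_thr, grid), q,
                clot_height(theta_B, vis_thr, grid), totals)
            log_lines.append(
                f"t={t:.3f}s q={q:.4g}uL/min vol={series.aggregate_volume[-1]:.4g}um3 "
                f"clamped={ws.clamped_mass:.3g} divmax={np.abs(solver.divergence(state)).max():.3g}")
            next_rec = t + rec_int
            if stop_on_occ:
                oc = occlusion_time(series, criterion)
                if oc != "not occluded":
                    occluded_at = oc
                    break
        if out_dir and vtk_int > 0 and t >= next_vtk - 1e-12:
            write_vtk(out_dir / f"fields_{step_i:06d}.vtk", grid, {
                "theta_B": fields.theta_B, "theta_T": fields.theta_T,
                "ADP": fields.ADP, "gamma_dot": gamma,
                "H_adh": adhesion.indicator})
            next_vtk = t + vtk_int
        dt_step = min(dt, t_end - t)
        fields = step_species(fields, state.velocity, params,
                              adhesion.indicator, dt_step, grid, gamma,
                              inlet_profiles=inlet_profiles,
                              eta_pseudo_dt=eta_pseudo_dt, workspace=ws)
        t += dt_step
        step_i += 1

    # final record
    theta_B = fields.theta_B
    q = _injury_flow(grid, state, cfg)
    if not series.times or t > series.times[-1] + 1e-9:
        totals = {n: float(getattr(fields, n)[grid.fluid].sum()
                           * grid.cell_volume)
                  for n in ("P_mu", "P_ma", "P_bvu", "P_bva", "P_bfa",
                            "P_seu", "P_sea")}
        series.append(t, aggregate_volume(theta_B, vis_thr, grid), q,
                      clot_height(theta_B, vis_thr, grid), totals)

    occ = {}
    for kind, thr in (("flow_threshold", 0.35), ("flow_fraction", 0.35)):
        occ[f"{kind}_{thr}"] = occlusion_time(
            series, OcclusionCriterion(kind, thr))
    occ["configured"] = (occluded_at if occluded_at is not None
                         else occlusion_time(series, criterion))

    diagnostics = {
        "steps": step_i,
        "clamped_mass": ws.clamped_mass,
        "max_theta_T": float(fields.theta_T.max()),
        "core_shell": core_shell_fractions(fields, vis_thr, grid),
        "final_time": t,
    }
    result = RunResult(cfg, grid, series, fields, state, occ, diagnostics,
                       out_dir)
    if out_dir:
        write_series_csv(out_dir / "series.csv", series.as_dict())
        write_summary_json(out_dir / "summary.json", {
            "name": cfg.name, "occlusion_times": occ,
            "diagnostics": diagnostics, "config": cfg.to_dict()})
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        write_vtk(out_dir / "final_fields.vtk", grid, {
            "theta_B": fields.theta_B, "theta_T": fields.theta_T,
            "ADP": fields.ADP, "gamma_dot": gamma,
            "H_adh": adhesion.indicator})
    return result
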