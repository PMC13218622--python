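"""Well-mixed (zero-dimensional) reduction of the platelet reaction network.

A single near-wall reaction volume at a fixed shear rate: the adhesion
indicator is 1, the virtual substances collapse to the bound fractions
(no spatial smoothing), and the mobile unactivated platelet density is
replenished by flow at the hindered-supply level C_in * W(theta_T), the 0D
analogue of advective resupply through a crowding aggregate (which also
saturates growth near maximum packing, as the hindered flux does in the full
model).  This is the cheap simulator used for parameter-space exploration and
calibration, and the reference system for the stiff-ODE oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    SPECIES,
    KineticParams,
    PlateletFields,
    evaluate_rate_table,
    reaction_rhs,
)

__all__ = ["WellMixedResult", "simulate_wellmixed", "wellmixed_rhs"]

_STATE = SPECIES + ("ADP", "adp_reservoir")


@dataclass
class WellMixedResult:
    times: np.ndarray
    states: dict          # name -> array over time
    theta_B: np.ndarray
    volume: np.ndarray    # um^3, theta_B * reference patch volume

    def volume_curve(self):
        return self.times, self.volume


def _fields_from_vector(y, P_max) -> PlateletFields:
    arrs = [np.asarray([v], dtype=float) for v in y]
    return PlateletFields(*arrs[:7], arrs[7], arrs[8], P_max)


def wellmixed_rhs(t, y, params: KineticParams, gamma_dot: float,
                  inlet_count: float, adp_on: bool = True,
                  clamp_mobile: bool = True):
    """Reaction RHS as a plain ODE vector field (order: 7 species, ADP, reservoir).

    With ``clamp_mobile`` the P_mu derivative is zeroed (held at the inlet
    density); with ``adp_on`` False the ADP pathway is disabled (the
    amplification-inhibited experimental condition).
    """
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    f = _fields_from_vector(y, params.P_max)
    eta_U = f.theta_U
    eta_A = f.theta_A
    d = reaction_rhs(f, np.asarray([gamma_dot], dtype=float), eta_U, eta_A,
                     np.asarray([1.0]), params, validate=False)
    out = np.array([float(d[n][0]) for n in _STATE])
    if not adp_on:
        out[_STATE.index("ADP")] = 0.0
        out[_STATE.index("adp_reservoir")] = 0.0
    if clamp_mobile:
        out[0] = 0.0
    return out


def simulate_wellmixed(
    params: KineticParams,
    gamma_dot: float,
    t_end: float,
    dt: float = 0.01,
    inlet_count: float = 2.5e5,
    adp_on: bool = False,
    record_every: int = 10,
    patch_volume_um3: float = 100.0 * 100.0 * 12.0,
) -> WellMixedResult:
    """Integrate the well-mixed network with RK4 and return metric curves.

    ``patch_volume_um3`` converts the bound fraction into a pseudo
    aggregate-volume curve comparable with straight-channel patch
    measurements (default: a 100x100 um^2 patch filled to 12 um height).
    """
    from .kinetics import hindrance_W

    n = int(round(t_end / dt))
    y = np.zeros(len(_STATE))
    y[0] = inlet_count
    times, rows = [], []
    for i in range(n + 1):
        t = i * dt
        # hindered advective resupply of the mobile pool (quasi-steady)
        theta_T = y[:7].sum() / params.P_max
        y[0] = inlet_count * hindrance_W(theta_T)
        if i % record_every == 0 or i == n:
            times.append(t)
            rows.append(y.copy())
        if i == n:
            break
        k1 = wellmixed_rhs(t, y, params, gamma_dot, inlet_count, adp_on)
        k2 = wellmixed_rhs(t, y + dt / 2 * k1, params, gamma_dot, inlet_count, adp_on)
        k3 = wellmixed_rhs(t, y + dt / 2 * k2, params, gamma_dot, inlet_count, adp_on)
        k4 = wellmixed_rhs(t, y + dt * k3, params, gamma_dot, inlet_count, adp_on)
        y = np.maximum(y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    rows = np.asarray(rows)
    states = {nme: rows[:, i] for i, nme in enumerate(_STATE)}
    theta_B = (states["P_bvu"] + states["P_bva"] + states["P_bfa"]
               + states["P_seu"] + states["P_sea"]) / params.P_max
    volume = theta_B * patch_volume_um3
    return WellMixedResult(np.asarray(times), states, theta_B, volume)
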