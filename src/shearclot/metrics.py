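"""Measurement layer: aggregate volume, clot height, occlusion time, structure.

These mirror the quantities used to compare the simulations against
microfluidic data: total supra-threshold aggregate volume over time, maximum
clot height above the reactive wall, occlusion time from the injury-channel
flow-rate series (median experimental criterion: flow below 0.35 uL/min), and
species-resolved isovolume masks for core–shell structure analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid
from .kinetics import PlateletFields

__all__ = [
    "ClotTimeSeries",
    "OcclusionCriterion",
    "NOT_OCCLUDED",
    "aggregate_volume",
    "occlusion_time",
    "clot_height",
    "species_isovolumes",
    "core_shell_fractions",
]

#: sentinel returned when the flow never crosses the occlusion threshold
NOT_OCCLUDED = "not occluded"

UM3_PER_MM3 = 1.0e9
UM_PER_MM = 1.0e3


@dataclass
class ClotTimeSeries:
    """Time series of scalar clot metrics recorded during a run."""

    times: list = field(default_factory=list)             # s
    aggregate_volume: list = field(default_factory=list)  # um^3
    injury_flow_rate: list = field(default_factory=list)  # uL/min
    max_clot_height: list = field(default_factory=list)   # um
    species_totals: dict = field(default_factory=dict)    # name -> list of plts

    def append(self, t, volume, flow=np.nan, height=np.nan, totals=None):
        if self.times and t <= self.times[-1]:
            raise ValueError("times must be strictly increasing")
        self.times.append(float(t))
        self.aggregate_volume.append(float(volume))
        self.injury_flow_rate.append(float(flow))
        self.max_clot_height.append(float(height))
        for k, v in (totals or {}).items():
            self.species_totals.setdefault(k, []).append(float(v))

    def as_dict(self) -> dict:
        out = {
            "time_s": list(self.times),
            "aggregate_volume_um3": list(self.aggregate_volume),
            "injury_flow_rate_uL_min": list(self.injury_flow_rate),
            "max_clot_height_um": list(self.max_clot_height),
        }
        for k, v in self.species_totals.items():
            out[f"total_{k}"] = list(v)
        return out


@dataclass
class OcclusionCriterion:
    """Occlusion definition: absolute flow threshold (uL/min) or fraction of initial flow."""

    kind: str = "flow_threshold"  # or "flow_fraction"
    threshold: float = 0.35

    def __post_init__(self):
        if self.kind not in ("flow_threshold", "flow_fraction"):
            raise ValueError(f"unknown occlusion criterion kind {self.kind!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def aggregate_volume(theta_B, vis_threshold: float, grid: Grid) -> float:
    """Total volume (um^3) of cells whose bound fraction exceeds the threshold."""
    if not 0.0 <= vis_threshold < 1.0:
        raise ValueError("vis_threshold must be in [0, 1)")
    t = np.asarray(theta_B)
    n = int(np.count_nonzero((t > vis_threshold) & grid.fluid))
    return n * grid.cell_volume * UM3_PER_MM3


def clot_height(theta_B, vis_threshold: float, grid: Grid,
                wall_axis: int | None = None, wall_side: str = "low") -> float:
    """Maximum distance (um) from the reactive wall of any supra-threshold cell."""
    if not 0.0 <= vis_threshold < 1.0:
        raise ValueError("vis_threshold must be in [0, 1)")
    if wall_axis is None:
        wall_axis = grid.ndim - 1
    t = np.asarray(theta_B)
    mask = (t > vis_threshold) & grid.fluid
    if not np.any(mask):
        return 0.0
    dist = grid.wall_distance(wall_axis, wall_side)
    h = grid.spacing[wall_axis]
    # height = far edge of the farthest supra-threshold cell
    return float((dist[mask].max() + h / 2) * UM_PER_MM)


def occlusion_time(series: ClotTimeSeries, criterion: OcclusionCriterion):
    """First time the flow rate falls to the threshold (linear interpolation).

    Returns the time in seconds, or the string ``"not occluded"``.
    """
    t = np.asarray(series.times, dtype=float)
    q = np.asarray(series.injury_flow_rate, dtype=float)
    if t.size == 0:
        raise ValueError("empty time series")
    if criterion.kind == "flow_fraction":
        q0 = q[np.isfinite(q)][0]
        thr = criterion.threshold * q0
    else:
        thr = criterion.threshold
    below = q <= thr
    if not np.any(below):
        return NOT_OCCLUDED
    i = int(np.argmax(below))
    if i == 0 or not np.isfinite(q[i - 1]):
        return float(t[i])
    # linear interpolation between the bracketing samples
    q1, q2 = q[i - 1], q[i]
    t1, t2 = t[i - 1], t[i]
    if q1 == q2:
        return float(t2)
    return float(t1 + (q1 - thr) / (q1 - q2) * (t2 - t1))


def species_isovolumes(fields: PlateletFields, thresholds=0.1) -> dict:
    """Indicator masks of the structural platelet classes.

    Returns masks (bool arrays) for:
      ``activated``          (P_bva + P_bfa + P_sea)/P_max > thr
      ``unactivated_bound``  (P_bvu + P_seu)/P_max > thr
      ``fibrinogen_bound``   P_bfa/P_max > thr
    ``thresholds`` may be a scalar or a dict keyed by class name.
    """
    if np.isscalar(thresholds):
        thr = {k: float(thresholds)
               for k in ("activated", "unactivated_bound", "fibrinogen_bound")}
    else:
        thr = dict(thresholds)
    for v in thr.values():
        if not 0.0 <= v < 1.0:
            raise ValueError("thresholds must be in [0, 1)")
    Pm = fields.P_max
    return {
        "activated": (fields.P_bva + fields.P_bfa + fields.P_sea) / Pm
        > thr["activated"],
        "unactivated_bound": (fields.P_bvu + fields.P_seu) / Pm
        > thr["unactivated_bound"],
        "fibrinogen_bound": fields.P_bfa / Pm > thr["fibrinogen_bound"],
    }


def core_shell_fractions(fields: PlateletFields, vis_threshold: float,
                         grid: Grid, wall_axis: int | None = None,
                         wall_side: str = "low") -> dict:
    """Activated-platelet fraction in the wall-proximal vs outer half of the clot.

    The clot is the supra-threshold bound region; it is split at half its
    maximum height above the reactive wall.  Returns the activated fraction
    (activated bound / all bound platelets) in each half — the core–shell
    architecture shows a higher activated fraction near the wall.
    """
    if wall_axis is None:
        wall_axis = grid.ndim - 1
    theta_B = fields.theta_B
    clot = (theta_B > vis_threshold) & grid.fluid
    if not np.any(clot):
        return {"wall_half": np.nan, "outer_half": np.nan}
    dist = grid.wall_distance(wall_axis, wall_side)
    hmax = dist[clot].max()
    inner = clot & (dist <= hmax / 2)
    outer = clot & (dist > hmax / 2)
    act = fields.P_bva + fields.P_bfa + fields.P_sea
    bound = act + fields.P_bvu + fields.P_seu

    def frac(m):
        b = bound[m].sum()
        return float(act[m].sum() / b) if b > 0 else np.nan

    return {"wall_half": frac(inner), "outer_half": frac(outer)}
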