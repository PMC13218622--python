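"""Structured computational domains for channel and bleeding-chip geometries.

All coordinates are physical, in mm, with a MAC/staggered layout: scalars live
at cell centers, velocity components on face centers.  Grids are 2D (x = flow,
y = wall-normal) or 3D (x = flow, y = width, z = height); the reactive wall is
the low side of the last axis in a straight channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import qmc

FLUID = 0
SOLID = 1

__all__ = [
    "Grid",
    "BoundaryPatch",
    "AdhesionRegion",
    "build_channel_grid",
    "build_bleeding_chip_grid",
    "generate_adhesion_region",
]


@dataclass
class BoundaryPatch:
    """A labelled opening on the domain boundary.

    kind is one of {"inflow", "outflow", "pressure"}; axis/side locate the
    boundary plane; extent restricts the patch to a physical box (or None for
    the whole plane).  "pressure" patches carry a prescribed pressure `value`
    (mPa); "inflow" patches carry a normal-velocity profile set at run time.
    """

    name: str
    kind: str
    axis: int
    side: str  # "low" | "high"
    extent: tuple | None = None
    value: float = 0.0

    def face_mask(self, grid: "Grid") -> np.ndarray:
        """Boolean mask over the boundary-plane cells covered by this patch."""
        cached = getattr(self, "_mask_cache", None)
        if cached is not None and cached[0] is grid:
            return cached[1]
        shape = tuple(n for a, n in enumerate(grid.dims) if a != self.axis)
        mask = np.ones(shape, dtype=bool)
        if self.extent is not None:
            axes = [a for a in range(grid.ndim) if a != self.axis]
            centers = np.meshgrid(
                *[grid.cell_centers(a) for a in axes], indexing="ij"
            )
            for (lo, hi), c in zip(self.extent, centers):
                mask &= (c >= lo - 1e-12) & (c <= hi + 1e-12)
        # restrict to fluid cells adjacent to the boundary
        idx = [slice(None)] * grid.ndim
        idx[self.axis] = 0 if self.side == "low" else grid.dims[self.axis] - 1
        mask &= grid.cell_mask[tuple(idx)] == FLUID
        object.__setattr__(self, "_mask_cache", (grid, mask))
        return mask


@dataclass
class Grid:
    dims: tuple
    spacing: tuple
    origin: tuple
    cell_mask: np.ndarray
    patches: list = field(default_factory=list)
    depth_mm: float = 0.05  # out-of-plane depth assumed for 2D volumetric rates

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def cell_volume(self) -> float:
        v = float(np.prod(self.spacing))
        if self.ndim == 2:
            v *= self.depth_mm
        return v

    @property
    def extents(self) -> tuple:
        return tuple(n * h for n, h in zip(self.dims, self.spacing))

    def cell_centers(self, axis: int) -> np.ndarray:
        n, h, o = self.dims[axis], self.spacing[axis], self.origin[axis]
        return o + (np.arange(n) + 0.5) * h

    def face_area(self, axis: int) -> float:
        """Area of a face normal to `axis` (mm^2; uses depth_mm in 2D)."""
        a = float(np.prod([self.spacing[b] for b in range(self.ndim) if b != axis]))
        if self.ndim == 2:
            a *= self.depth_mm
        return a

    @property
    def fluid(self) -> np.ndarray:
        return self.cell_mask == FLUID

    def n_fluid_cells(self) -> int:
        return int(np.count_nonzero(self.fluid))

    def fluid_connected(self) -> bool:
        """True when the fluid region is one connected component (face adjacency)."""
        labels, n = ndimage.label(self.fluid)
        return n == 1

    def patch_by_name(self, name: str) -> BoundaryPatch:
        for p in self.patches:
            if p.name == name:
                return p
        raise KeyError(name)

    def wall_distance(self, axis: int, side: str = "low") -> np.ndarray:
        """Distance of each cell center from the given domain-boundary wall."""
        c = self.cell_centers(axis)
        if side == "low":
            d = c - self.origin[axis]
        else:
            d = self.origin[axis] + self.extents[axis] - c
        shape = [1] * self.ndim
        shape[axis] = -1
        return np.broadcast_to(d.reshape(shape), self.dims).copy()


def _n_cells(extent: float, spacing: float, name: str) -> int:
    if extent <= 0:
        raise ValueError(f"{name} must be positive, got {extent}")
    if spacing > extent:
        raise ValueError(
            f"spacing {spacing} mm is larger than {name} extent {extent} mm"
        )
    n = int(round(extent / spacing))
    if abs(n * spacing - extent) > spacing:
        raise ValueError(
            f"spacing {spacing} does not divide {name} extent {extent} to within one cell"
        )
    return max(n, 2)


def build_channel_grid(
    length_mm: float,
    width_mm: float,
    height_mm: float | None,
    spacing_mm: float,
    mode_2d: bool = False,
) -> Grid:
    """Rectangular duct with one inflow (x=0), one outflow (x=L), no-slip walls.

    In 2D mode the grid is x (flow) by `width_mm` (wall-normal); the third axis
    is absent and ``width_mm`` plays the role of the channel height.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    nx = _n_cells(length_mm, spacing_mm, "length")
    ny = _n_cells(width_mm, spacing_mm, "width")
    if mode_2d:
        dims = (nx, ny)
        depth = height_mm if height_mm else width_mm
    else:
        if height_mm is None:
            raise ValueError("height_mm is required in 3D mode")
        nz = _n_cells(height_mm, spacing_mm, "height")
        dims = (nx, ny, nz)
        depth = height_mm
    mask = np.zeros(dims, dtype=np.int8)
    patches = [
        BoundaryPatch("inlet", "inflow", axis=0, side="low"),
        BoundaryPatch("outlet", "pressure", axis=0, side="high", value=0.0),
    ]
    return Grid(
        dims=dims,
        spacing=(spacing_mm,) * len(dims),
        origin=(0.0,) * len(dims),
        cell_mask=mask,
        patches=patches,
        depth_mm=depth,
    )


def build_bleeding_chip_grid(
    blood_channel_dims: tuple,
    wash_channel_dims: tuple,
    injury_channel_dims: tuple,
    spacing_mm: float,
    mode_2d: bool = True,
    junction_frac: float = 0.5,
) -> Grid:
    """H-shaped bleeding-chip domain: two parallel ducts bridged by an injury channel.

    Channel dims are (length, width[, height]) in mm.  The wash channel runs
    along x at low y, the blood channel along x at high y, and the injury
    channel (length = gap in y, width = extent in x) bridges them at
    ``junction_frac`` of the channel length (0.5 = mid-channel; smaller values
    move the injury toward the inlets, which raises the blood-side junction
    pressure and with it the injury-channel shear).
    Each duct has its own inflow (x=0) and pressure outlet (x=L).  In 3D all
    three channels share the same height (third component of the dims).
    """
    lb, wb = blood_channel_dims[0], blood_channel_dims[1]
    lw, ww = wash_channel_dims[0], wash_channel_dims[1]
    li, wi = injury_channel_dims[0], injury_channel_dims[1]
    for v, nm in [(lb, "blood length"), (wb, "blood width"), (lw, "wash length"),
                  (ww, "wash width"), (li, "injury length"), (wi, "injury width")]:
        if v <= 0:
            raise ValueError(f"{nm} must be positive")
    length = max(lb, lw)
    total_w = ww + li + wb
    nx = _n_cells(length, spacing_mm, "channel length")
    ny = _n_cells(total_w, spacing_mm, "total width")
    if mode_2d:
        dims = (nx, ny)
        height = blood_channel_dims[2] if len(blood_channel_dims) > 2 else 0.05
    else:
        height = blood_channel_dims[2]
        nz = _n_cells(height, spacing_mm, "height")
        dims = (nx, ny, nz)
    mask = np.full(dims, SOLID, dtype=np.int8)
    x = np.arange(nx) * spacing_mm + spacing_mm / 2
    y = np.arange(ny) * spacing_mm + spacing_mm / 2
    X, Y = np.meshgrid(x, y, indexing="ij")
    wash = (Y < ww) & (X < lw)
    blood = (Y > ww + li) & (Y < total_w) & (X < lb)
    if not 0.0 < junction_frac < 1.0:
        raise ValueError("junction_frac must be in (0, 1)")
    x0 = junction_frac * length - wi / 2.0
    x0 = min(max(x0, spacing_mm), length - wi - spacing_mm)
    injury = (X > x0) & (X < x0 + wi) & (Y >= ww - spacing_mm / 2) & (
        Y <= ww + li + spacing_mm / 2
    )
    fluid2d = wash | blood | injury
    if mode_2d:
        mask[fluid2d] = FLUID
    else:
        mask[fluid2d, :] = FLUID
    grid = Grid(
        dims=dims,
        spacing=(spacing_mm,) * len(dims),
        origin=(0.0,) * len(dims),
        cell_mask=mask,
        patches=[
            BoundaryPatch("wash_in", "inflow", axis=0, side="low",
                          extent=_chip_extent(0.0, ww, height, mode_2d)),
            BoundaryPatch("wash_out", "pressure", axis=0, side="high",
                          extent=_chip_extent(0.0, ww, height, mode_2d)),
            BoundaryPatch("blood_in", "inflow", axis=0, side="low",
                          extent=_chip_extent(ww + li, total_w, height, mode_2d)),
            BoundaryPatch("blood_out", "pressure", axis=0, side="high",
                          extent=_chip_extent(ww + li, total_w, height, mode_2d)),
        ],
        depth_mm=height,
    )
    if not grid.fluid_connected():
        raise ValueError(
            "bleeding-chip topology is disconnected: the injury channel does "
            "not bridge both ducts"
        )
    # injury-channel bounding box (used by scenarios for adhesion + metering)
    grid.injury_box = ((x0, x0 + wi), (ww, ww + li))
    return grid


def _chip_extent(y0, y1, height, mode_2d):
    if mode_2d:
        return ((y0, y1),)
    return ((y0, y1), (0.0, height))


@dataclass
class AdhesionRegion:
    """Indicator field H_adh marking near-wall cells eligible for adhesion."""

    indicator: np.ndarray
    patch_extent: tuple
    platelet_diameter: float
    site_fraction: float
    seed: int

    def fraction_selected(self, eligible: np.ndarray) -> float:
        n = int(np.count_nonzero(eligible))
        return float(np.count_nonzero(self.indicator[eligible] > 0)) / max(n, 1)


def generate_adhesion_region(
    grid: Grid,
    patch_extent: tuple,
    platelet_diameter: float,
    site_fraction: float = 1.0,
    seed: int = 0,
    wall_axis: int | None = None,
    wall_side: str = "low",
) -> AdhesionRegion:
    """Quasi-random selection of near-wall adhesion sites over a wall patch.

    ``patch_extent`` is a tuple of (lo, hi) intervals over the wall-tangential
    axes (one interval in 2D, two in 3D).  Eligible cells are fluid cells whose
    center lies within one platelet diameter of the reactive wall (the first
    cell layer is always eligible) and inside the patch footprint.  A Halton
    low-discrepancy sequence selects a ``site_fraction`` of the footprint
    columns; site_fraction=1 reproduces the dense "unity within one platelet
    diameter" convention.  Deterministic for a fixed seed.
    """
    if not 0.0 <= site_fraction <= 1.0:
        raise ValueError("site_fraction must be in [0, 1]")
    if wall_axis is None:
        wall_axis = grid.ndim - 1
    tang_axes = [a for a in range(grid.ndim) if a != wall_axis]
    if len(patch_extent) != len(tang_axes):
        raise ValueError("patch_extent must give one interval per tangential axis")
    for (lo, hi), a in zip(patch_extent, tang_axes):
        if lo < grid.origin[a] - 1e-12 or hi > grid.origin[a] + grid.extents[a] + 1e-12:
            raise ValueError("patch_extent does not lie on the wall plane")

    dist = grid.wall_distance(wall_axis, wall_side)
    layer_idx = np.zeros(grid.dims, dtype=int)
    idx = np.arange(grid.dims[wall_axis])
    if wall_side == "high":
        idx = idx[::-1]
    shape = [1] * grid.ndim
    shape[wall_axis] = -1
    layer_idx += idx.reshape(shape)
    near_wall = (dist <= platelet_diameter + 1e-12) | (layer_idx == 0)

    in_patch = np.ones(grid.dims, dtype=bool)
    for (lo, hi), a in zip(patch_extent, tang_axes):
        c = grid.cell_centers(a)
        m = (c >= lo - 1e-12) & (c <= hi + 1e-12)
        sh = [1] * grid.ndim
        sh[a] = -1
        in_patch &= m.reshape(sh)

    eligible = near_wall & in_patch & grid.fluid
    indicator = np.zeros(grid.dims, dtype=np.float64)
    if site_fraction >= 1.0:
        indicator[eligible] = 1.0
        return AdhesionRegion(indicator, patch_extent, platelet_diameter,
                              site_fraction, seed)

    # columns = footprint cells over tangential axes
    col_mask = eligible.any(axis=wall_axis)
    cols = np.argwhere(col_mask)
    n_cols = len(cols)
    target = int(round(site_fraction * n_cols))
    if target > 0 and n_cols > 0:
        lows = np.array([patch_extent[k][0] for k in range(len(tang_axes))])
        highs = np.array([patch_extent[k][1] for k in range(len(tang_axes))])
        sampler = qmc.Halton(d=len(tang_axes), seed=seed)
        chosen: set = set()
        # oversample until `target` distinct columns are hit
        while len(chosen) < target:
            pts = sampler.random(max(4 * target, 64))
            phys = lows + pts * (highs - lows)
            for p in phys:
                key = tuple(
                    int(np.clip((p[k] - grid.origin[a]) / grid.spacing[a],
                                0, grid.dims[a] - 1))
                    for k, a in enumerate(tang_axes)
                )
                if col_mask[key]:
                    chosen.add(key)
                    if len(chosen) >= target:
                        break
        sel = np.zeros_like(col_mask)
        for key in chosen:
            sel[key] = True
        indicator[np.expand_dims(sel, wall_axis) & eligible] = 1.0
    return AdhesionRegion(indicator, patch_extent, platelet_diameter,
                          site_fraction, seed)
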