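# Methods

## Model

`shearclot` simulates platelet aggregation under flow as a continuum. Blood is
an incompressible Newtonian fluid; a growing aggregate acts on it through a
volumetric Brinkman drag `-mu * alpha(theta_B) * u` with a Carman–Kozeny
resistance

    alpha(theta_B) = C_CK (0.6 theta_B)^2 / (1 - 0.6 theta_B)^3,
    C_CK = 1e6 mm^-2,

where `theta_B` is the bound-platelet number fraction (total bound density /
maximum packing density `P_max`). Platelets are tracked as seven number-density
fields — mobile or bound, activated or not, bound via vWF, fibrin(ogen) or the
subendothelium — plus the soluble agonist ADP. Mobile species and ADP move by
hindered advection–diffusion: all fluxes are scaled by
`W(theta_T) = tanh(pi (1 - theta_T))`, which shuts transport off as the local
total platelet fraction `theta_T` approaches packing. Bound species do not
move.

Adhesion, cohesion and activation through vWF depend on the local shear rate
`gamma = sqrt(2 D:D)`. Each shear-dependent rate is a `RateFunction` anchored
at the two calibration shears (300/s, value `a`) and (1500/s, value `b`), with
a linear segment between them and a configurable extrapolation beyond 2000/s:

* `linear` — unlimited linear extrapolation (clamped at zero below);
* `piecewise_linear` — the linear form held constant beyond a truncation
  shear (2000, 5000, 8000 or 10000 /s);
* `tanh_saturating` — linear to `transition_start` (2000/s), then a sigmoidal
  bridge that reaches the linear value extrapolated to `transition_end`
  (8000/s) and stays constant: a faster-than-linear rise at intermediate
  shear with saturation where vWF is fully extended (used for on-rates);
* `exponential_saturating` — linear to 2000/s, then an exponential approach
  to the same asymptote with e-folding shear `(te - ts)/shape`; with
  `shape = 1` the slope is also continuous at the transition (used for
  off-rates: a slower-than-linear rise in unbinding);
* `constant` — shear-independent control (pinned at the 300/s value).

The tanh bridge is value-continuous at both ends of the transition by
construction; exact slope continuity at `transition_start` is traded for
hitting the plateau exactly at `transition_end` (the exponential form keeps
slope continuity instead). On (2000, 8000)/s the forms order pointwise:
trunc@2000 <= exponential < trunc@8000 <= linear (for `b > a`), which is the
bond-lifetime ordering that controls occlusion at high shear.

Cohesion uses the binding-affinity function

    g(eta) = g0 (eta - eta_t)^3 / (eta*^3 + (eta - eta_t)),
    g0 = (eta*^3 + (1 - eta_t)) / (1 - eta_t)^3,

zero below the threshold `eta_t` and normalized so `g(1) = 1`. Its arguments
are two *virtual substances* `eta_U`, `eta_A` — the unactivated-bound and
activated-bound fractions diffused over one platelet diameter by a single
implicit diffusion solve — which give point densities the finite interaction
neighborhood of a real platelet and prevent double counting between
vWF-mediated and fibrinogen-mediated cohesion.

The reaction network (fluxes per unit volume):

* mobile unactivated platelets adhere to the subendothelial adhesion region
  `H_adh` via vWF (reversible, shear-dependent) and via collagen
  (irreversible, `k_adh_col`), jointly gated by `(1 - theta_B)` site
  availability;
* mobile platelets cohere to bound ones via vWF at
  `k_coh_vwf_on(gamma) [g(eta_U) + g(eta_A)] P_max`, reversibly;
* subendothelial and vWF-bound platelets are activated by collagen
  (`k_act_col`), shear (`k_act_vwf(gamma)`) or ADP (Hill law, half-maximal at
  `adp_act_threshold`); activation terms carry a smooth guard that vanishes
  where `theta_T` is below `theta_floor`, preventing spurious activation of
  the dilute continuum;
* activated bound platelets cohere irreversibly through fibrin(ogen)
  (`k_coh_fbg g(eta_A) P_max`); mobile activated platelets bind the
  subendothelium irreversibly;
* newly activated bound platelets charge a per-volume ADP reservoir
  (`adp_release_total` mol/platelet) that releases over
  `adp_release_duration`; ADP is transported and diluted but not consumed.

The seven species' reaction terms cancel pointwise, so reactions conserve
platelet number exactly; the test suite checks this to machine precision over
random states.

## Numerics

Structured MAC/staggered grids (cell-centered scalars, face-normal
velocities), physical units mm–s–mg (pressure in mPa), 2D and 3D. The flow is
solved in two modes:

* **Quasi-static (default for scenarios).** Clot growth is slow (seconds to
  minutes) compared with viscous relaxation (`h^2/nu` is sub-millisecond at
  these scales), so the steady Stokes–Brinkman system is re-solved at a fixed
  simulated-time interval (default 0.05 s) as `alpha(theta_B)` evolves.
  Inertia is dropped: the Reynolds number is below ~0.2 in every scenario.
  The coupled velocity–pressure system is assembled sparse and solved
  directly, which satisfies the divergence constraint to solver precision.
* **Transient (reference).** One implicit step of the Navier–Stokes–Brinkman
  equations: explicit first-order upwind advection; viscous, Brinkman and
  pressure terms solved monolithically with backward Euler. The monolithic
  form was chosen over a predictor–corrector splitting because it reuses the
  steady assembler and makes each step exactly divergence-free; backward
  Euler (rather than Crank–Nicolson) costs temporal order that none of the
  steady-profile validations depend on.

Boundary conditions: prescribed inflow velocity profiles (parabolic; the
amplitude for a target wall shear rate is fixed exactly by one clean-channel
solve, exploiting the linearity of Stokes flow), prescribed-pressure outlets,
no-slip walls via mirrored ghosts; internal solid cells are excluded from the
system with zero-velocity faces (staircase immersed boundaries). Shear rates
are evaluated at cell centers with mirrored ghosts at no-slip walls, so the
wall-adjacent shear of a resolved Poiseuille profile is recovered to
discretization error. Validation: Poiseuille and Poiseuille–Brinkman channel
profiles match the closed forms within 1% at 2.5 um resolution with
second-order grid convergence.

Species transport uses a conservative finite-volume update with van-Leer
limited upwind advection and explicit central diffusion; the face hindrance
factor is the *minimum* of the adjacent cells' `W` values, so a saturated
cell closes its faces entirely — this is what bounds `theta_T` near 1
(averaging W would leave faces half-open against a packed cell). Explicit
diffusion was chosen over implicit because the advective CFL bound is far
stricter than the diffusive bound at every resolution and diffusivity used
here; the stepper raises an error if the combined explicit stability bound
would be violated, rather than silently losing stability. The timestep is
`cfl_safety / (|u|max/h + 2 d Dmax/h^2)` with `cfl_safety = 0.5`.

Reactions are decoupled from transport by a fractional step and integrated
pointwise with classical RK4 at half the transport timestep (two sub-steps),
restricted to the active cell set (cells where some flux can be nonzero:
adhesion region, nonzero bound density, ADP, or a virtual substance above
`eta_t`) — outside it every reaction term vanishes identically. Limiter
undershoots are clamped at zero and the clamped mass is logged per run.
RK4 order is verified by sub-step halving (~16x error decay) and the whole
reaction path against an independent stiff solver (Radau) to 1e-6 relative
over 10 s.

The adhesion region is a Halton low-discrepancy selection of near-wall cells
over the patch footprint: deterministic for a fixed seed, with `site_fraction`
of eligible cells selected; `site_fraction = 1` reproduces the dense
"unity within one platelet diameter" convention. On the bleeding chip the
eligible set is the first cell layers along the injury-channel walls
(Euclidean distance transform against the solid mask).

## Parameters

Defaults (placeholders where the source values are not published; the
calibration harness exists to refit them):

| parameter | default | units | note |
|---|---|---|---|
| rho, mu | 1.06, 3.5 | mg/mm^3, mg/(mm s) | whole blood (3.5 cP) |
| C_CK | 1e6 | mm^-2 | Carman–Kozeny coefficient |
| P_max | 6.67e7 | plts/mm^3 | maximum packing density |
| inlet count | 2.5e5 | plts/mm^3 | physiological 250k/uL |
| margination | 2.5x, 3 um | —, mm | near-wall enhancement, layer |
| D_P, D_eta, D_ADP | 2.5e-5, 2.5e-5, 2.5e-4 | mm^2/s | effective diffusivities |
| k_adh_vwf_on (a, b) | 2e-9, 1.2e-8 | mm^3/(plt s) | placeholder |
| k_adh_vwf_off (a, b) | 0.05, 0.3 | 1/s | placeholder |
| k_coh_vwf_on (a, b) | 8e-10, 8e-9 | mm^3/(plt s) | placeholder |
| k_coh_vwf_off (a, b) | 0.03, 0.2 | 1/s | placeholder |
| k_adh_col | 1e-9 | mm^3/(plt s) | irreversible collagen adhesion |
| k_coh_fbg | 3e-7 | mm^3/(plt s) | irreversible fibrinogen cohesion |
| k_act_col | 0.5 | 1/s | collagen (GPVI) activation |
| k_act_vwf (a, b) | 2e-3, 3e-1 | 1/s | shear activation, floor 100/s |
| eta_t, eta* | 0.1, 0.3 | — | binding-affinity threshold/width |
| ADP activation | 0.34 1/s, 0.5 uM, Hill 2 | | guard floor theta_floor = 1e-4 |
| ADP release | 4e-17 mol/plt over 5 s | | finite-duration secretion |

The vWF rate anchors are *effective* rates: the on-rates multiply `P_max` (so
`k_on * P_max` is the 1/s capture rate at full site availability), and the
`(a, b)` pairs were set, in the spirit of the original calibration procedure,
so that the well-mixed reduction and the coarse 2D scenarios produce
wall-layer filling followed by cohesive multilayer growth, with unbinding
competitive with activation at high shear (that competition is what makes the
off-rate families distinguishable).

## Scenarios and demo scaling

Shipped presets cover the two experiment families: the straight channel
(160 x 150 x 50 um computational domain with a 100 x 100 um^2 adhesion patch,
wall shear 300/s or 1500/s, ADP amplification on = "control" or off =
"inhibited") and a parameterized H-shaped bleeding chip (blood channel and
wider, faster-flowing wash channel bridged by an injury channel; injury flow
driven blood-to-wash by the junction pressure difference; occlusion judged by
the flow at the wash end of the injury channel, threshold 0.35 uL/min, the
median experimental criterion).

The `*_demo` presets are the desk-scale study conditions used by the test
suite and examples: coarse 2D grids (2.5 um cells), kinetic rates multiplied
by `rate_scale` (50x channel, 300x chip) and platelet-enriched inlet blood
(1e7 plts/mm^3), which together compress minutes of platelet delivery and
growth into a few seconds of simulated time while leaving the model structure,
the shear field and the rate-family ordering intact. The per-platelet ADP
release total is divided by the same enrichment factor in the demo presets so
agonist concentrations stay at their physiological-scale values. Because
reversible vWF bonds turn over in fractions of a second at demo rates, the
unactivated outer shell of the demo clots is thin: the robust part of the
core–shell contrast at this scale is the enrichment of activated platelets
against the collagen surface. The chip demo runs in
the amplification-inhibited condition so the shear-dependent vWF pathway—
the thing the rate families differ in — controls occlusion rather than the
shear-independent ADP/fibrinogen loop, and its "constant" control pins the
vWF activation rate as well as the four binding rates (a fully
shear-independent model). Demo virtual-substance smoothing uses a 4 um
diffusion length (1.6 cells) so the cohesion neighborhood of a packed layer
reaches past the adjacent cell center on the coarse grid. What the demo runs
show is therefore directional (orderings, structure), not quantitative
agreement with the full-scale experiments.

## Calibration harness

Two-stage sequential grid search: for each parameter in list order, a
multiplicative sweep (coarse: ±2 orders of magnitude; refined: ±1 order
centered on the coarse optimum; step factors 2–5) minimizing the summed SSE
between simulated and target aggregate-volume curves (simulated curves
linearly interpolated to the target sample times). The default simulator
callback is the well-mixed reduction: a single near-wall volume at fixed
shear with `H_adh = 1`, virtual substances collapsed to the bound fractions,
and the mobile pool replenished at the hindered-supply level
`C_in W(theta_T)` (the 0D analogue of advective resupply through a crowding
aggregate, which also saturates growth near packing). Failed grid points are
logged and skipped; all points within 5% of the best objective are reported,
surfacing non-identifiability. Synthetic targets (well-mixed curve + seeded
Gaussian noise) make parameter-recovery tests self-contained.

## Known limitations

* Newtonian rheology; no RBC mechanics (margination is imposed at the inlet,
  not emergent), no viscoelastic clot deformation or embolization, no
  coagulation chemistry.
* Staircase immersed boundaries at internal walls are first-order accurate;
  domain-boundary walls are second-order.
* The printed binding-affinity denominator mixes a cubic and a linear term in
  a dimensionless argument; it is implemented exactly as printed and
  normalized so g(1) = 1.
* TVD-limited advection degrades to first order at smooth extrema; the
  Gaussian-pulse validation quantifies this (variance within 2% at 0.25 um
  resolution).
* Well-mixed calibration identifies cohesion anchors only in regimes where
  the bound fraction crosses `eta_t` within the simulated window; the
  recovery tests run at the accelerated demo scale for that reason.
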