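"""Shear-dependent kinetic rate laws and the seven-species platelet reaction network.

The model tracks seven platelet number-density fields (plts/mm^3):

==========  =====================================================
``P_mu``    mobile, unactivated
``P_ma``    mobile, aggregatory (activated)
``P_bvu``   bound via vWF, unactivated
``P_bva``   bound via vWF, aggregatory and secretory
``P_bfa``   bound via fibrin(ogen), aggregatory and secretory
``P_seu``   subendothelial-bound via vWF, unactivated
``P_sea``   subendothelial-bound via collagen, aggregatory/secretory
==========  =====================================================

plus the soluble agonist ADP (uM) and an internal per-volume reservoir of
yet-to-be-released ADP carried by newly activated bound platelets.

vWF-mediated adhesion, cohesion and activation rates depend on the local shear
rate through :class:`RateFunction`: every non-constant form passes through the
anchors (300/s, a) and (1500/s, b) measured in the straight-channel
calibration, and the forms differ in how they extrapolate beyond the 2000/s
calibration window (truncated piecewise-linear, tanh-saturating on-rates,
exponentially saturating off-rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RateFunction",
    "KineticParams",
    "PlateletFields",
    "SPECIES",
    "evaluate_rate",
    "binding_affinity_g",
    "hindrance_W",
    "adp_activation_rate",
    "activation_guard",
    "reaction_rhs",
    "default_params",
]

SPECIES = ("P_mu", "P_ma", "P_bvu", "P_bva", "P_bfa", "P_seu", "P_sea")
BOUND_SPECIES = ("P_bvu", "P_bva", "P_bfa", "P_seu", "P_sea")
MOBILE_SPECIES = ("P_mu", "P_ma")

#: uM per (mol / mm^3): 1 uM = 1e-12 mol/mm^3
MOL_PER_MM3_TO_UM = 1.0e12

RATE_FORMS = ("linear", "piecewise_linear", "tanh_saturating",
              "exponential_saturating", "constant")


@dataclass(frozen=True)
class RateFunction:
    """A shear-dependent kinetic rate k(shear) anchored at 300/s and 1500/s.

    Parameters
    ----------
    form : one of ``linear | piecewise_linear | tanh_saturating |
        exponential_saturating | constant``.
    a, b : rate values at shear 300/s and 1500/s (anchor points of the linear
        segment; same units as the rate itself).
    truncation_shear : 1/s; piecewise-linear forms hold the linear value
        constant beyond this shear.
    transition_start, transition_end : 1/s; saturating forms follow the linear
        segment up to ``transition_start`` and plateau at the linear value
        extrapolated to ``transition_end``.
    shape : dimensionless steepness (tanh) or e-folding count (exponential) of
        the transition.
    activation_threshold : 1/s; the rate is zero below this shear (used for
        shear-induced activation, 0 disables the floor).
    """

    form: str = "linear"
    a: float = 0.0
    b: float = 0.0
    truncation_shear: float = 10000.0
    transition_start: float = 2000.0
    transition_end: float = 8000.0
    shape: float = 4.0
    activation_threshold: float = 0.0

    def __post_init__(self):
        if self.form not in RATE_FORMS:
            raise ValueError(f"unknown rate form {self.form!r}")

    def __call__(self, gamma_dot):
        return evaluate_rate(self, gamma_dot)

    def to_dict(self) -> dict:
        return {
            "form": self.form, "a": self.a, "b": self.b,
            "truncation_shear": self.truncation_shear,
            "transition_start": self.transition_start,
            "transition_end": self.transition_end,
            "shape": self.shape,
            "activation_threshold": self.activation_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateFunction":
        return cls(**d)


def _linear(rf: RateFunction, g):
    return rf.a + (g - 300.0) / 1200.0 * (rf.b - rf.a)


def evaluate_rate(rf: RateFunction, gamma_dot):
    """Evaluate a shear-dependent rate at shear rate(s) ``gamma_dot`` (1/s).

    All non-constant forms share the linear segment
    ``a + (gamma - 300)/1200 * (b - a)`` pinned to the two calibration shears;
    results are clamped at zero so extrapolation below 300/s cannot produce a
    negative rate.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be nonnegative")
    if rf.form == "constant":
        out = np.full_like(g, rf.a)
    elif rf.form == "linear":
        out = _linear(rf, g)
    elif rf.form == "piecewise_linear":
        out = _linear(rf, np.minimum(g, rf.truncation_shear))
    elif rf.form == "tanh_saturating":
        ts, te = rf.transition_start, rf.transition_end
        lo = _linear(rf, np.minimum(g, ts))
        k_start = _linear(rf, ts)
        k_end = _linear(rf, te)
        x = np.clip((g - ts) / (te - ts), 0.0, 1.0)
        s0 = rf.shape
        # sigmoidal bridge: exactly k_start at x=0 and k_end at x=1
        w = (np.tanh(s0 * (x - 0.5)) + np.tanh(s0 / 2)) / (2 * np.tanh(s0 / 2))
        out = np.where(g <= ts, lo, k_start + (k_end - k_start) * w)
    elif rf.form == "exponential_saturating":
        ts, te = rf.transition_start, rf.transition_end
        lo = _linear(rf, np.minimum(g, ts))
        k_start = _linear(rf, ts)
        k_end = _linear(rf, te)
        lam = (te - ts) / rf.shape  # e-folding shear; shape=1 matches the
        # linear slope at the transition when the asymptote sits at k(te)
        decay = np.exp(-np.maximum(g - ts, 0.0) / lam)
        out = np.where(g <= ts, lo, k_end - (k_end - k_start) * decay)
    else:  # pragma: no cover
        raise ValueError(rf.form)
    if rf.activation_threshold > 0:
        out = np.where(g < rf.activation_threshold, 0.0, out)
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def binding_affinity_g(eta, eta_t: float, eta_star: float):
    """vWF cohesion binding-affinity g(eta), zero below eta_t, normalized so g(1)=1.

    g(eta) = g0 (eta - eta_t)^3 / (eta*^3 + (eta - eta_t)) with
    g0 = (eta*^3 + (1 - eta_t)) / (1 - eta_t)^3.
    """
    if eta_t >= 1.0 or eta_t < 0.0:
        raise ValueError("eta_t must satisfy 0 <= eta_t < 1")
    if eta_star <= 0.0:
        raise ValueError("eta_star must be positive")
    e = np.asarray(eta, dtype=float)
    g0 = (eta_star**3 + (1.0 - eta_t)) / (1.0 - eta_t) ** 3
    x = np.maximum(e - eta_t, 0.0)
    out = g0 * x**3 / (eta_star**3 + x)
    return out if out.ndim else float(out)


def hindrance_W(theta_T):
    """Hindered-transport factor W = tanh(pi (1 - theta_T)), clamped to 0 above 1."""
    t = np.asarray(theta_T, dtype=float)
    out = np.tanh(np.pi * np.maximum(1.0 - t, 0.0))
    return out if out.ndim else float(out)


def adp_activation_rate(adp, params: "KineticParams"):
    """ADP-induced activation rate A_ADP([ADP]) in 1/s (Hill form).

    Zero at zero concentration, half-maximal at ``adp_act_threshold`` and
    saturating at ``adp_act_rate``.
    """
    c = np.asarray(adp, dtype=float)
    if np.any(c < 0):
        raise ValueError("ADP concentration must be nonnegative")
    n = params.adp_act_hill
    c50 = params.adp_act_threshold
    cn = c**n
    out = params.adp_act_rate * cn / (cn + c50**n)
    return out if out.ndim else float(out)


def activation_guard(theta_T, theta_floor: float):
    """Smooth indicator suppressing activation where the local platelet fraction
    is negligible (guards against spurious activation of the dilute continuum).

    0 for theta_T <= theta_floor, 1 for theta_T >= 2*theta_floor, cubic
    smoothstep in between.
    """
    t = np.asarray(theta_T, dtype=float)
    x = np.clip((t - theta_floor) / max(theta_floor, 1e-300), 0.0, 1.0)
    out = x * x * (3.0 - 2.0 * x)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KineticParams:
    """Full kinetic parameter bundle.

    vWF on-rates are in mm^3/(plt s) (they multiply P_max to give 1/s),
    off-rates in 1/s.  Defaults are placeholder values from the prior
    continuum-hemostasis model family; see docs/methods.md.
    """

    k_adh_vwf_on: RateFunction = field(
        default_factory=lambda: RateFunction("linear", a=2.0e-9, b=1.2e-8))
    k_adh_vwf_off: RateFunction = field(
        default_factory=lambda: RateFunction("linear", a=0.05, b=0.75))
    k_coh_vwf_on: RateFunction = field(
        default_factory=lambda: RateFunction("linear", a=8.0e-10, b=8.0e-9))
    k_coh_vwf_off: RateFunction = field(
        default_factory=lambda: RateFunction("linear", a=0.03, b=0.5))
    k_adh_col: float = 1.0e-9          # mm^3/(plt s), irreversible collagen adhesion
    k_coh_fbg: float = 3.0e-7          # mm^3/(plt s), irreversible fibrinogen cohesion
    k_act_vwf: RateFunction = field(
        default_factory=lambda: RateFunction(
            "linear", a=2.0e-3, b=3.0e-1, activation_threshold=100.0))
    k_act_col: float = 0.5             # 1/s
    eta_t: float = 0.1
    eta_star: float = 0.3
    P_max: float = 6.67e7              # plts/mm^3 (max packing density)
    D_P: float = 2.5e-5                # mm^2/s platelet diffusivity
    D_eta: float = 2.5e-5              # mm^2/s virtual-substance diffusivity
    D_ADP: float = 2.5e-4              # mm^2/s
    adp_act_threshold: float = 0.5     # uM, half-max of the Hill activation law
    adp_act_rate: float = 0.34         # 1/s, saturating ADP activation rate
    adp_act_hill: float = 2.0
    adp_release_total: float = 4.0e-17  # mol ADP released per activated platelet
    adp_release_duration: float = 5.0  # s
    theta_floor: float = 1.0e-4        # activation guard threshold on theta_T

    def __post_init__(self):
        if not (0.0 <= self.eta_t < 1.0):
            raise ValueError("eta_t must be in [0, 1)")
        if self.eta_star <= 0 or self.P_max <= 0:
            raise ValueError("eta_star and P_max must be positive")
        for name in ("k_adh_col", "k_coh_fbg", "k_act_col"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def scaled(self, rate_scale: float) -> "KineticParams":
        """Return a copy with every kinetic rate multiplied by ``rate_scale``.

        Used by the desk-scale demo scenarios, which compress minutes of clot
        growth into a few seconds of simulated time.
        """

        def srf(rf: RateFunction) -> RateFunction:
            return replace(rf, a=rf.a * rate_scale, b=rf.b * rate_scale)

        return replace(
            self,
            k_adh_vwf_on=srf(self.k_adh_vwf_on),
            k_adh_vwf_off=srf(self.k_adh_vwf_off),
            k_coh_vwf_on=srf(self.k_coh_vwf_on),
            k_coh_vwf_off=srf(self.k_coh_vwf_off),
            k_act_vwf=srf(self.k_act_vwf),
            k_adh_col=self.k_adh_col * rate_scale,
            k_coh_fbg=self.k_coh_fbg * rate_scale,
            k_act_col=self.k_act_col * rate_scale,
            adp_act_rate=self.adp_act_rate * rate_scale,
            adp_release_duration=self.adp_release_duration / rate_scale,
        )


def default_params(**overrides) -> KineticParams:
    return replace(KineticParams(), **overrides) if overrides else KineticParams()


@dataclass
class PlateletFields:
    """The seven platelet number-density fields, ADP, and the ADP reservoir.

    ``adp_reservoir`` (uM-equivalent per mm^3 of tissue) tracks granule ADP
    carried by newly activated bound platelets and released over a finite
    duration; it is attached to immobile platelets and is not transported.
    """

    P_mu: np.ndarray
    P_ma: np.ndarray
    P_bvu: np.ndarray
    P_bva: np.ndarray
    P_bfa: np.ndarray
    P_seu: np.ndarray
    P_sea: np.ndarray
    ADP: np.ndarray
    adp_reservoir: np.ndarray
    P_max: float

    @classmethod
    def zeros(cls, shape, P_max: float) -> "PlateletFields":
        z = lambda: np.zeros(shape, dtype=np.float64)
        return cls(z(), z(), z(), z(), z(), z(), z(), z(), z(), P_max)

    def species(self) -> dict:
        return {name: getattr(self, name) for name in SPECIES}

    @property
    def theta_B(self) -> np.ndarray:
        return (self.P_bvu + self.P_bva + self.P_bfa + self.P_seu
                + self.P_sea) / self.P_max

    @property
    def theta_T(self) -> np.ndarray:
        return (self.P_mu + self.P_ma + self.P_bvu + self.P_bva + self.P_bfa
                + self.P_seu + self.P_sea) / self.P_max

    @property
    def theta_U(self) -> np.ndarray:
        """Unactivated bound fraction (P_bvu + P_seu)/P_max."""
        return (self.P_bvu + self.P_seu) / self.P_max

    @property
    def theta_A(self) -> np.ndarray:
        """Activated bound fraction (P_bva + P_bfa + P_sea)/P_max."""
        return (self.P_bva + self.P_bfa + self.P_sea) / self.P_max

    def copy(self) -> "PlateletFields":
        return PlateletFields(
            *(getattr(self, n).copy() for n in SPECIES),
            self.ADP.copy(), self.adp_reservoir.copy(), self.P_max)

    def total_platelets(self) -> np.ndarray:
        return sum(getattr(self, n) for n in SPECIES)


@dataclass(frozen=True)
class RateTable:
    """Shear-dependent rates pre-evaluated on a gamma-dot field (cache helper)."""

    k_adh_on: np.ndarray
    k_adh_off: np.ndarray
    k_coh_on: np.ndarray
    k_coh_off: np.ndarray
    k_act_vwf: np.ndarray


def evaluate_rate_table(params: KineticParams, gamma_dot) -> RateTable:
    return RateTable(
        k_adh_on=np.asarray(evaluate_rate(params.k_adh_vwf_on, gamma_dot)),
        k_adh_off=np.asarray(evaluate_rate(params.k_adh_vwf_off, gamma_dot)),
        k_coh_on=np.asarray(evaluate_rate(params.k_coh_vwf_on, gamma_dot)),
        k_coh_off=np.asarray(evaluate_rate(params.k_coh_vwf_off, gamma_dot)),
        k_act_vwf=np.asarray(evaluate_rate(params.k_act_vwf, gamma_dot)),
    )


def reaction_rhs(
    fields: PlateletFields,
    gamma_dot,
    eta_U,
    eta_A,
    H_adh,
    params: KineticParams,
    rates: RateTable | None = None,
    validate: bool = True,
) -> dict:
    """Pointwise reaction right-hand side for the seven species, ADP and the reservoir.

    Implements the vWF transition network: reversible vWF adhesion/cohesion,
    irreversible collagen adhesion and fibrinogen cohesion, activation by
    collagen, shear (through vWF bonds) and ADP, and finite-duration ADP
    secretion by newly activated bound platelets.  The seven species terms sum
    to zero pointwise (platelet number is conserved by reactions).
    """
    if validate:
        for name in SPECIES + ("ADP",):
            arr = np.asarray(getattr(fields, name))
            if np.any(np.isnan(arr)):
                raise ValueError(f"NaN encountered in field {name}")
            if np.any(arr < 0):
                raise ValueError(f"negative density in field {name}")
    if rates is None:
        rates = evaluate_rate_table(params, gamma_dot)
    Pmax = params.P_max
    P_mu, P_ma = fields.P_mu, fields.P_ma
    P_bvu, P_bva, P_bfa = fields.P_bvu, fields.P_bva, fields.P_bfa
    P_seu, P_sea = fields.P_seu, fields.P_sea

    theta_B = fields.theta_B
    theta_T = fields.theta_T
    avail = np.maximum(1.0 - theta_B, 0.0)

    gU = binding_affinity_g(eta_U, params.eta_t, params.eta_star)
    gA = binding_affinity_g(eta_A, params.eta_t, params.eta_star)
    g_sum = gU + gA

    guard = activation_guard(theta_T, params.theta_floor)
    A_adp = adp_activation_rate(fields.ADP, params) * guard
    k_shear_act = rates.k_act_vwf * guard

    se_capture = (rates.k_adh_on + params.k_adh_col) * H_adh * Pmax * avail

    # --- fluxes (plts/mm^3/s); F_x_y moves density from species x to y
    F_mu_seu_v = rates.k_adh_on * H_adh * Pmax * avail * P_mu   # reversible vWF
    F_mu_seu_c = params.k_adh_col * H_adh * Pmax * avail * P_mu  # irreversible col
    F_seu_mu = rates.k_adh_off * P_seu
    F_mu_bvu = rates.k_coh_on * g_sum * Pmax * P_mu
    F_bvu_mu = rates.k_coh_off * P_bvu
    F_mu_ma = A_adp * P_mu
    F_seu_sea = (params.k_act_col + k_shear_act + A_adp) * P_seu
    F_bvu_seu = se_capture * P_bvu
    F_bvu_bva = (k_shear_act + A_adp) * P_bvu
    F_bva_bfa = params.k_coh_fbg * gA * Pmax * P_bva
    F_ma_bva = rates.k_coh_on * g_sum * Pmax * P_ma
    F_bva_ma = rates.k_coh_off * P_bva
    F_ma_sea = se_capture * P_ma            # irreversible for activated platelets
    F_ma_bfa = params.k_coh_fbg * gA * Pmax * P_ma

    d = {
        "P_mu": (-F_mu_seu_v - F_mu_seu_c + F_seu_mu - F_mu_bvu + F_bvu_mu
                 - F_mu_ma),
        "P_ma": (F_mu_ma - F_ma_bva + F_bva_ma - F_ma_sea - F_ma_bfa),
        "P_bvu": (F_mu_bvu - F_bvu_mu - F_bvu_seu - F_bvu_bva),
        "P_bva": (F_bvu_bva + F_ma_bva - F_bva_ma - F_bva_bfa),
        "P_bfa": (F_bva_bfa + F_ma_bfa),
        "P_seu": (F_mu_seu_v + F_mu_seu_c - F_seu_mu + F_bvu_seu - F_seu_sea),
        "P_sea": (F_seu_sea + F_ma_sea),
    }

    # ADP secretion: newly activated *bound* platelets charge the reservoir,
    # which releases over adp_release_duration.  (Mobile activated platelets
    # secrete only once bound, hence the F_ma_* fluxes below.)
    newly_secreting = F_seu_sea + F_bvu_bva + F_ma_sea + F_ma_bva + F_ma_bfa
    charge = (params.adp_release_total * MOL_PER_MM3_TO_UM) * newly_secreting
    release = fields.adp_reservoir / params.adp_release_duration
    d["adp_reservoir"] = charge - release
    d["ADP"] = release
    return d
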