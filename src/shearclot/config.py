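"""Run configuration: YAML round-trip, scenario presets, reproducibility plumbing.

A :class:`RunConfig` is a plain nested-dict configuration with blocks for
geometry, fluid, kinetics, adhesion, inlet, transport, metrics and simulation
control.  Every run writes its resolved configuration next to its outputs.

The preset catalog ships the two experiment families:

* straight channel (160 x 150 x 50 um duct, 100 x 100 um^2 adhesion patch) at
  wall shear 300/s and 1500/s, each with the ADP amplification loop enabled
  ("control") or disabled ("inhibited", the calibration condition);
* the H-shaped bleeding chip with constant, piecewise-linear-truncated, or
  tanh-on + exponential-off vWF rate families.

``*_demo`` presets are coarse 2D, kinetics-accelerated versions of the same
scenarios that run in minutes on a laptop; see docs/methods.md.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import yaml

from .kinetics import KineticParams, RateFunction, default_params

__all__ = ["RunConfig", "load_config", "save_config", "list_presets",
           "get_preset", "kinetics_from_config", "kinetics_to_config"]


@dataclass
class RunConfig:
    name: str = "run"
    geometry: dict = field(default_factory=dict)
    fluid: dict = field(default_factory=lambda: {
        "rho": 1.06, "mu": 3.5, "C_CK": 1.0e6})
    kinetics: dict = field(default_factory=dict)
    adhesion: dict = field(default_factory=lambda: {
        "platelet_diameter": 0.003, "site_fraction": 1.0})
    inlet: dict = field(default_factory=lambda: {
        "mean_count": 2.5e5, "enhancement": 2.5, "layer_thickness": 0.003})
    transport: dict = field(default_factory=lambda: {
        "cfl_safety": 0.5, "flow_update_interval": 0.05,
        "eta_diffusion_length": None})
    metrics: dict = field(default_factory=lambda: {
        "vis_threshold": 0.1, "record_interval": 0.25,
        "occlusion": {"kind": "flow_threshold", "threshold": 0.35},
        "vtk_interval": 0.0})
    simulation: dict = field(default_factory=lambda: {
        "t_end": 10.0, "adp_on": True, "stop_on_occlusion": False})
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name, "geometry": self.geometry, "fluid": self.fluid,
            "kinetics": self.kinetics, "adhesion": self.adhesion,
            "inlet": self.inlet, "transport": self.transport,
            "metrics": self.metrics, "simulation": self.simulation,
            "seed": self.seed, "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        base = cls()
        out = cls(**{**base.to_dict(), **d})
        return out

    def copy(self) -> "RunConfig":
        return RunConfig.from_dict(copy.deepcopy(self.to_dict()))


def save_config(cfg: RunConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return path


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


# ------------------------------------------------------------- kinetics <-> dict

_RATE_FIELDS = ("k_adh_vwf_on", "k_adh_vwf_off", "k_coh_vwf_on",
                "k_coh_vwf_off", "k_act_vwf")


def kinetics_to_config(params: KineticParams, rate_scale: float = 1.0) -> dict:
    d = {"rate_scale": rate_scale}
    for name in _RATE_FIELDS:
        d[name] = getattr(params, name).to_dict()
    for name in ("k_adh_col", "k_coh_fbg", "k_act_col", "eta_t", "eta_star",
                 "P_max", "D_P", "D_eta", "D_ADP", "adp_act_threshold",
                 "adp_act_rate", "adp_act_hill", "adp_release_total",
                 "adp_release_duration", "theta_floor"):
        d[name] = getattr(params, name)
    return d


def kinetics_from_config(d: dict) -> KineticParams:
    d = dict(d or {})
    rate_scale = float(d.pop("rate_scale", 1.0))
    kwargs = {}
    for name in _RATE_FIELDS:
        if name in d:
            v = d.pop(name)
            kwargs[name] = RateFunction.from_dict(v) if isinstance(v, dict) else v
    kwargs.update(d)
    p = default_params(**kwargs)
    return p.scaled(rate_scale) if rate_scale != 1.0 else p


# ---------------------------------------------------------------- rate families

def rate_family(family: str, params: KineticParams) -> KineticParams:
    """Apply one of the shear-extrapolation families to the four vWF rates.

    family:
      "constant"  — shear-independent rates pinned at the 300/s values
      "linear"    — unlimited linear extrapolation
      "piecewise" — on-rates truncated at 8000/s, off-rates at 8000/s
      "piecewise_off2000" — off-rates plateau from 2000/s (on-rates at 10000/s)
      "tanh_trunc8000"    — tanh-saturating on-rates, off-rates truncated at 8000/s
      "tanh_exp"  — tanh-saturating on-rates + exponentially saturating
                    off-rates (the best-performing pair)
    """
    def on(rf, form, trunc=10000.0):
        return replace(rf, form=form, truncation_shear=trunc)

    if family == "constant":
        # fully shear-independent control: adhesion, cohesion and vWF
        # activation all pinned at their 300/s values
        return replace(
            params,
            k_adh_vwf_on=replace(params.k_adh_vwf_on, form="constant"),
            k_adh_vwf_off=replace(params.k_adh_vwf_off, form="constant"),
            k_coh_vwf_on=replace(params.k_coh_vwf_on, form="constant"),
            k_coh_vwf_off=replace(params.k_coh_vwf_off, form="constant"),
            k_act_vwf=replace(params.k_act_vwf, form="constant"),
        )
    if family == "linear":
        forms = dict(on_form="linear", off_form="linear")
    elif family == "piecewise":
        forms = dict(on_form="piecewise_linear", on_trunc=8000.0,
                     off_form="piecewise_linear", off_trunc=8000.0)
    elif family == "piecewise_off2000":
        forms = dict(on_form="piecewise_linear", on_trunc=10000.0,
                     off_form="piecewise_linear", off_trunc=2000.0)
    elif family == "tanh_trunc8000":
        forms = dict(on_form="tanh_saturating",
                     off_form="piecewise_linear", off_trunc=8000.0)
    elif family == "tanh_exp":
        forms = dict(on_form="tanh_saturating", off_form="exponential_saturating")
    else:
        raise ValueError(f"unknown rate family {family!r}")
    on_form = forms.get("on_form", "linear")
    off_form = forms.get("off_form", "linear")
    on_trunc = forms.get("on_trunc", 10000.0)
    off_trunc = forms.get("off_trunc", 10000.0)
    return replace(
        params,
        k_adh_vwf_on=on(params.k_adh_vwf_on, on_form, on_trunc),
        k_adh_vwf_off=on(params.k_adh_vwf_off, off_form, off_trunc),
        k_coh_vwf_on=on(params.k_coh_vwf_on, on_form, on_trunc),
        k_coh_vwf_off=on(params.k_coh_vwf_off, off_form, off_trunc),
    )


# -------------------------------------------------------------------- presets

def _channel_config(shear: float, adp_on: bool, demo: bool) -> RunConfig:
    cfg = RunConfig()
    tag = "control" if adp_on else "inhibited"
    cfg.name = f"straight_channel_{int(shear)}_{tag}" + ("_demo" if demo else "")
    if demo:
        # coarse 2D slice of the duct with accelerated kinetics
        cfg.geometry = {"kind": "channel", "length": 0.16, "width": 0.05,
                        "height": 0.05, "spacing": 0.0025, "mode_2d": True}
        cfg.kinetics = kinetics_to_config(default_params(), rate_scale=50.0)
        cfg.adhesion.update({"patch_extent": [[0.03, 0.13]]})
        # platelet-enriched demo blood (see docs/methods.md on demo scaling);
        # per-platelet ADP release is divided by the same enrichment factor so
        # agonist concentrations stay at their physiological-scale values
        cfg.inlet["mean_count"] = 1.0e7
        cfg.kinetics["adp_release_total"] = 1.0e-18
        cfg.simulation = {"t_end": 8.0, "adp_on": adp_on,
                          "stop_on_occlusion": False}
        cfg.metrics["record_interval"] = 0.25
    else:
        cfg.geometry = {"kind": "channel", "length": 0.16, "width": 0.15,
                        "height": 0.05, "spacing": 0.005, "mode_2d": False}
        cfg.kinetics = kinetics_to_config(default_params())
        cfg.adhesion.update({"patch_extent": [[0.03, 0.13], [0.025, 0.125]]})
        cfg.simulation = {"t_end": 450.0, "adp_on": adp_on,
                          "stop_on_occlusion": False}
        cfg.metrics["record_interval"] = 5.0
    cfg.fluid["wall_shear"] = shear
    return cfg


def _chip_config(family: str, demo: bool) -> RunConfig:
    cfg = RunConfig()
    cfg.name = f"bleeding_chip_{family}" + ("_demo" if demo else "")
    params = rate_family(family, default_params())
    if demo:
        # narrow blood channel + wide wash channel put the blood-side junction
        # at the higher pressure, driving injury flow blood -> wash; the wash
        # carries the larger volumetric flow at a lower mean velocity.
        cfg.geometry = {"kind": "chip", "spacing": 0.0025, "mode_2d": True,
                        "junction_frac": 0.33,
                        "blood_channel": [0.15, 0.02, 0.05],
                        "wash_channel": [0.15, 0.05, 0.05],
                        "injury_channel": [0.02, 0.015, 0.05]}
        # velocities sized so the injury-channel wall shear starts ~2500/s,
        # inside the window where the extrapolation families diverge
        cfg.fluid["blood_mean_velocity"] = 12.0  # mm/s
        cfg.fluid["wash_mean_velocity"] = 10.0
        # platelet-enriched demo blood: compresses the platelet delivery that
        # takes minutes at physiological counts into seconds (methods note)
        cfg.inlet["mean_count"] = 1.0e7
        # cohesion neighborhood must span >1.5 cells on the coarse demo grid
        cfg.transport["eta_diffusion_length"] = 0.005
        cfg.kinetics = kinetics_to_config(params, rate_scale=300.0)
        # amplification-inhibited condition: isolates the vWF shear dependence
        # that distinguishes the rate families
        cfg.simulation = {"t_end": 4.5, "adp_on": False,
                          "stop_on_occlusion": True}
        cfg.metrics["record_interval"] = 0.2
        cfg.metrics["occlusion"] = {"kind": "flow_fraction", "threshold": 0.35}
    else:
        cfg.geometry = {"kind": "chip", "spacing": 0.005, "mode_2d": False,
                        "blood_channel": [1.0, 0.05, 0.05],
                        "wash_channel": [1.0, 0.1, 0.05],
                        "injury_channel": [0.15, 0.05, 0.05]}
        cfg.fluid["blood_mean_velocity"] = 10.0
        cfg.fluid["wash_mean_velocity"] = 20.0
        cfg.kinetics = kinetics_to_config(params)
        cfg.simulation = {"t_end": 600.0, "adp_on": True,
                          "stop_on_occlusion": True}
        cfg.metrics["record_interval"] = 5.0
        cfg.metrics["occlusion"] = {"kind": "flow_threshold", "threshold": 0.35}
    return cfg


_PRESET_BUILDERS = {}
for _shear in (300, 1500):
    for _adp, _tag in ((True, "control"), (False, "inhibited")):
        for _demo in (False, True):
            _nm = f"straight_channel_{_shear}_{_tag}" + ("_demo" if _demo else "")
            _PRESET_BUILDERS[_nm] = (
                lambda s=_shear, a=_adp, d=_demo: _channel_config(s, a, d))
for _family in ("constant", "piecewise", "piecewise_off2000",
                "tanh_trunc8000", "tanh_exp"):
    for _demo in (False, True):
        _nm = f"bleeding_chip_{_family}" + ("_demo" if _demo else "")
        _PRESET_BUILDERS[_nm] = (lambda f=_family, d=_demo: _chip_config(f, d))

_DESCRIPTIONS = {
    "straight_channel": "rectangular duct over a collagen/vWF adhesion patch",
    "bleeding_chip": "H-shaped extravascular-injury chip",
}


def list_presets() -> dict:
    """Shipped scenario presets with one-line descriptions."""
    out = {}
    for name in sorted(_PRESET_BUILDERS):
        kind = "straight_channel" if name.startswith("straight") else "bleeding_chip"
        extra = " (coarse 2D demo, accelerated kinetics)" if name.endswith("_demo") else ""
        out[name] = _DESCRIPTIONS[kind] + extra
    return out


def get_preset(name: str) -> RunConfig:
    try:
        return _PRESET_BUILDERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESET_BUILDERS)}")
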