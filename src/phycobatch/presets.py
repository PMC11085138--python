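"""Calibrated simulation presets.

The YAML file shipped with the package describes the default study
conditions (vessel geometry, sampling, noise, replicate count) and a set of
named scenarios whose kinetic anchors are the magnitudes the corresponding
published experiments report.  ``mu_max`` is resolved from each anchor at
load time:

* ``target_initial_rate`` — closed-form inversion of the depth-averaged
  rate at the inoculum density;
* ``target_vmax`` — root-finding on the noiseless simulator so that the
  peak volumetric productivity of the trajectory equals the anchor.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import yaml
from scipy.optimize import brentq

from .calibration import CalibrationModel
from .errors import DomainError
from .simulate import CultureSpec, depth_averaged_rate, simulate_photoautotrophic

__all__ = [
    "available_presets",
    "load_preset",
    "mu_max_for_initial_rate",
    "mu_max_for_target_vmax",
]


def _raw() -> dict:
    ref = importlib.resources.files("phycobatch") / "data" / "presets.yaml"
    return yaml.safe_load(ref.read_text())


def available_presets() -> list[str]:
    raw = _raw()
    return [name for group in raw.values() for name in group["scenarios"]]


def mu_max_for_initial_rate(target: float, spec: CultureSpec) -> float:
    """mu_max giving an initial specific growth rate of ``target`` at X0.

    Inverts mu0 = mu_bar(X0; mu_max) - maintenance, which is linear in
    mu_max for the depth-averaged closed form.
    """
    unit = depth_averaged_rate(spec.X0, CultureSpec(**{**spec.__dict__, "mu_max": 1.0}))
    if unit <= 0:
        raise DomainError("no light reaches the culture; cannot anchor the initial rate")
    return (target + spec.maintenance) / unit


def mu_max_for_target_vmax(target: float, spec: CultureSpec,
                           lo: float = 0.005, hi: float = 2.0) -> float:
    """mu_max such that the noiseless trajectory's peak productivity is ``target``.

    Peak productivity is max_t 24 dX/dt (g L^-1 day^-1) over the sampled
    run; it increases monotonically with mu_max, so a bracketed root search
    on the simulator converges quickly.
    """

    def peak(mu_max: float) -> float:
        s = CultureSpec(**{**spec.__dict__, "mu_max": mu_max})
        return simulate_photoautotrophic(s).truth["peak_productivity_per_day"] - target

    return float(brentq(peak, lo, hi, xtol=1e-6))


def load_preset(name: str, seed: int = 0, **overrides) -> CultureSpec:
    """Build the :class:`CultureSpec` for a named scenario.

    ``overrides`` replace spec fields after anchor resolution, except the
    fields the anchors depend on (I0, X0, geometry), which are applied
    before resolving so anchored ground truths stay exact.  For the
    ``light_scan`` scenario pass ``I0=...`` per run; mu_max stays anchored
    to the reference intensity, emulating one strain measured at several
    intensities.
    """
    raw = _raw()
    for group in raw.values():
        if name in group["scenarios"]:
            fields = dict(group["base"])
            fields.update(group["scenarios"][name])
            break
    else:
        raise KeyError(f"unknown preset {name!r}; available: {available_presets()}")

    target_mu0 = fields.pop("target_initial_rate", None)
    anchored_at = fields.pop("target_initial_rate_at", None)
    target_vmax = fields.pop("target_vmax", None)
    cal = fields.pop("calibration", None)
    if cal is not None:
        fields["calibration"] = CalibrationModel(a=cal["a"], b=cal["b"], label=name)
    fields["seed"] = seed
    fields["label"] = name
    fields.update(overrides)
    spec = CultureSpec(**fields)
    if anchored_at is not None:
        rate, ref_I0 = anchored_at
        ref = CultureSpec(**{**spec.__dict__, "I0": float(ref_I0)})
        spec = CultureSpec(**{**spec.__dict__, "mu_max": mu_max_for_initial_rate(float(rate), ref)})
    elif target_mu0 is not None:
        spec = CultureSpec(**{**spec.__dict__, "mu_max": mu_max_for_initial_rate(target_mu0, spec)})
    elif target_vmax is not None:
        spec = CultureSpec(**{**spec.__dict__, "mu_max": mu_max_for_target_vmax(target_vmax, spec)})
    return spec
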