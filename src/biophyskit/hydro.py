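"""Closed-form hydrodynamic predictions for a globular protein.

Forward predictions only: the anhydrous sphere radius, the Svedberg
sedimentation coefficient for a given frictional ratio, standardization of
an observed s to water at 20 C (s20,w), and the Stokes–Einstein–Debye
rotational correlation time of a hydrated sphere.  These are the desk
checks used to decide whether a measured s or a fluorescence-derived
rotational correlation time is consistent with a monomer of given mass.

Units follow analytical-ultracentrifugation convention: mass in Da,
partial specific volume (vbar) in mL/g, viscosity in poise, density in
g/mL, temperature in K; sedimentation coefficients in svedberg (1e-13 s),
correlation times in ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO, BOLTZMANN, ETA_20W_POISE, RHO_20W, SVEDBERG

__all__ = [
    "HydroSpec",
    "anhydrous_radius",
    "sedimentation_coefficient",
    "s20w_correction",
    "rotational_correlation",
    "hydro_report",
]

HYDRATION_CONVENTIONS = ("volume-fraction", "mass-hydration", "radius-scale")


@dataclass
class HydroSpec:
    """Inputs for hydrodynamic predictions.

    ``hydration`` is interpreted according to the convention passed to
    :func:`rotational_correlation` (volume fraction, g water per g protein,
    or fractional radius increase).
    """

    mass: float  # Da
    vbar: float = 0.73  # mL/g
    viscosity: float = ETA_20W_POISE  # poise
    density: float = RHO_20W  # g/mL
    temperature: float = 293.15  # K
    frictional_ratio: float = 1.0
    hydration: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mass", "vbar", "viscosity", "density", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frictional_ratio < 1.0:
            raise ValueError("frictional ratio must be >= 1")
        if self.hydration < 0:
            raise ValueError("hydration must be non-negative")


def anhydrous_radius(mass: float, vbar: float) -> float:
    """Radius (nm) of the anhydrous sphere of given mass (Da) and vbar (mL/g).

    R0 = (3 M vbar / (4 pi N_A))^(1/3); the minimal sphere whose friction
    defines f0 in the frictional ratio.
    """
    if mass <= 0 or vbar <= 0:
        raise ValueError("mass and vbar must be positive")
    volume_cm3 = mass * vbar / AVOGADRO  # per molecule
    radius_cm = (3.0 * volume_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return radius_cm * 1e7


def sedimentation_coefficient(spec: HydroSpec) -> float:
    """Svedberg prediction s = M (1 - vbar rho) / (N_A (f/f0) 6 pi eta R0).

    Evaluated in CGS units (mass Da, viscosity poise, R0 cm) and reported
    in svedberg.  Neutral buoyancy returns 0 with a warning.
    """
    buoyancy = 1.0 - spec.vbar * spec.density
    if buoyancy <= 0:
        warnings.warn("neutrally or negatively buoyant species", stacklevel=2)
        if buoyancy == 0:
            return 0.0
    r0_cm = anhydrous_radius(spec.mass, spec.vbar) * 1e-7
    f0 = 6.0 * np.pi * spec.viscosity * r0_cm  # g/s per molecule
    s_seconds = spec.mass * buoyancy / (AVOGADRO * spec.frictional_ratio * f0)
    return s_seconds / SVEDBERG


def s20w_correction(s_obs: float, buffer: HydroSpec, vbar: float | None = None) -> float:
    """Standardize an observed s to water at 20 C.

    s20,w = s_obs (eta_buffer / eta_20,w) * (1 - vbar rho)_20,w / (1 - vbar rho)_buffer
    """
    vbar = buffer.vbar if vbar is None else vbar
    buoy_buffer = 1.0 - vbar * buffer.density
    buoy_std = 1.0 - vbar * RHO_20W
    if buoy_buffer <= 0 or buoy_std <= 0:
        raise ValueError("neutral buoyancy; s20,w undefined")
    return s_obs * (buffer.viscosity / ETA_20W_POISE) * (buoy_std / buoy_buffer)


def rotational_correlation(spec: HydroSpec, hydration_convention: str) -> float:
    """Stokes–Einstein–Debye rotational correlation time (ns).

    theta = eta V_h / (k_B T) with the hydrated volume V_h per molecule
    set by an explicit convention for ``spec.hydration``:

    * ``volume-fraction``: V_h = (M/N_A) vbar (1 + phi)
    * ``mass-hydration``:  V_h = (M/N_A) (vbar + delta * 1.0 mL/g)
    * ``radius-scale``:    V_h = (M/N_A) vbar (1 + eps)^3

    The three readings of a loosely stated "hydration" differ by tens of
    percent, so no default convention is assumed.
    """
    if hydration_convention not in HYDRATION_CONVENTIONS:
        raise ValueError(
            f"unknown hydration convention {hydration_convention!r}; "
            f"choose one of {HYDRATION_CONVENTIONS}"
        )
    h = spec.hydration
    base_cm3 = spec.mass * spec.vbar / AVOGADRO
    if hydration_convention == "volume-fraction":
        v_h = base_cm3 * (1.0 + h)
    elif hydration_convention == "mass-hydration":
        v_h = spec.mass * (spec.vbar + h * 1.0) / AVOGADRO
    else:  # radius-scale
        v_h = base_cm3 * (1.0 + h) ** 3
    eta_si = spec.viscosity * 0.1  # poise -> Pa s
    v_si = v_h * 1e-6  # cm3 -> m3
    theta_s = eta_si * v_si / (BOLTZMANN * spec.temperature)
    return theta_s * 1e9


def hydro_report(spec: HydroSpec, hydration_convention: str = "radius-scale") -> dict:
    """Audit-ready report: inputs, constants and every closed-form output."""
    return {
        "inputs": {
            "mass_Da": spec.mass,
            "vbar_mL_per_g": spec.vbar,
            "viscosity_poise": spec.viscosity,
            "density_g_per_mL": spec.density,
            "temperature_K": spec.temperature,
            "frictional_ratio": spec.frictional_ratio,
            "hydration": spec.hydration,
            "hydration_convention": hydration_convention,
        },
        "constants": {
            "N_A_per_mol": AVOGADRO,
            "k_B_J_per_K": BOLTZMANN,
            "eta_20w_poise": ETA_20W_POISE,
            "rho_20w_g_per_mL": RHO_20W,
        },
        "formulas": {
            "anhydrous_radius": "R0 = (3 M vbar / (4 pi N_A))^(1/3)",
            "sedimentation_coefficient": (
                "s = M (1 - vbar rho) / (N_A (f/f0) 6 pi eta R0)"
            ),
            "rotational_correlation": "theta = eta V_h / (k_B T)",
        },
        "outputs": {
            "anhydrous_radius_nm": anhydrous_radius(spec.mass, spec.vbar),
            "sedimentation_coefficient_S": sedimentation_coefficient(spec),
            "rotational_correlation_ns": rotational_correlation(
                spec, hydration_convention
            ),
        },
    }
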