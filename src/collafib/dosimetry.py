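"""Photon-physics and energy-balance arithmetic.

keV <-> J conversion, wavelength from photon energy, absorbed energy from
dose x mass, and thermal energy from heat capacity.  Constants are pinned
to the rounded values in :mod:`collafib.constants` so printed-precision
round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import ELEMENTARY_CHARGE_C, PLANCK_J_S, SPEED_OF_LIGHT_M_S


@dataclass(frozen=True)
class PhotonSpec:
    energy_keV: float
    energy_J: float
    wavelength_nm: float
    source_label: str = ""


@dataclass(frozen=True)
class EnergyBudget:
    dose_Gy: float
    mass_kg: float
    absorbed_J: float
    heat_capacity_J_per_kgC: float | None = None
    delta_T_C: float | None = None
    thermal_J: float | None = None


def energy_J_from_keV(energy_keV: float) -> float:
    """Photon energy in joules: E[keV] * 1e3 * e."""
    if energy_keV <= 0:
        raise ValueError("photon energy must be positive")
    return energy_keV * 1e3 * ELEMENTARY_CHARGE_C


def wavelength_nm(energy_J: float) -> float:
    """Photon wavelength h*c/E expressed in nm."""
    if energy_J <= 0:
        raise ValueError("photon energy must be positive")
    return PLANCK_J_S * SPEED_OF_LIGHT_M_S / energy_J * 1e9


def photon_from_keV(energy_keV: float, source_label: str = "") -> PhotonSpec:
    """Full photon record (energy in J, wavelength in nm) from energy in keV."""
    e_J = energy_J_from_keV(energy_keV)
    return PhotonSpec(
        energy_keV=energy_keV,
        energy_J=e_J,
        wavelength_nm=wavelength_nm(e_J),
        source_label=source_label,
    )


def energy_budget(
    dose_Gy: float,
    mass_kg: float,
    heat_capacity_J_per_kgC: float | None = None,
    delta_T_C: float | None = None,
) -> EnergyBudget:
    """Absorbed energy dose*mass, plus thermal energy m*c_p*dT when given.

    Both outputs are exact products of their inputs; no attenuation or
    transport modelling.
    """
    if dose_Gy < 0 or mass_kg < 0:
        raise ValueError("dose and mass must be non-negative")
    thermal = None
    if heat_capacity_J_per_kgC is not None and delta_T_C is not None:
        if heat_capacity_J_per_kgC < 0 or delta_T_C < 0:
            raise ValueError("heat capacity and temperature rise must be non-negative")
        thermal = mass_kg * heat_capacity_J_per_kgC * delta_T_C
    return EnergyBudget(
        dose_Gy=dose_Gy,
        mass_kg=mass_kg,
        absorbed_J=dose_Gy * mass_kg,
        heat_capacity_J_per_kgC=heat_capacity_J_per_kgC,
        delta_T_C=delta_T_C,
        thermal_J=thermal,
    )
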