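"""Physical constants and unit helpers.

Conventions used throughout the package:

* coordinates in angstrom, time in ns, energies in kT unless a unit suffix
  says otherwise, voltages in mV, currents in pA, conductances in pS.
* the z axis is the membrane normal and positive z points extracellular.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import constants as _sc

#: default simulation temperature (K)
DEFAULT_TEMPERATURE = 303.15

#: calories per joule conversion used for kcal/mol
_CAL = 4184.0


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA physical constants (SI units)."""

    e: float = _sc.e               # elementary charge, C
    k_B: float = _sc.k             # Boltzmann constant, J/K
    N_A: float = _sc.N_A           # Avogadro constant, 1/mol
    F: float = _sc.e * _sc.N_A     # Faraday constant, C/mol
    R: float = _sc.k * _sc.N_A     # gas constant, J/mol/K
    eps0: float = _sc.epsilon_0    # vacuum permittivity, F/m


CONSTANTS = PhysicalConstants()


def kT_joule(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in joules."""
    return CONSTANTS.k_B * temperature


def kT_kcal_per_mol(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol (0.6024 at 303.15 K)."""
    return CONSTANTS.k_B * temperature * CONSTANTS.N_A / _CAL


def kT_mV(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal voltage k_B*T/e in mV (~26.1 mV at 303.15 K)."""
    return CONSTANTS.k_B * temperature / CONSTANTS.e * 1e3


def reduced_voltage(voltage_mV: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Reduced membrane potential u = e*V/kT for V in mV."""
    return voltage_mV / kT_mV(temperature)
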