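"""Physical constants and unit conversions.

All internal energies are in units of k_B T at the working temperature;
lengths are in Angstrom, charges in units of the elementary charge e,
concentrations in mol/L unless a number density (1/A^3) is explicitly asked
for. Conversions are centralized here so no magic numbers leak into the
physics modules.
"""

from __future__ import annotations

#: Coulomb constant e^2 / (4 pi eps_0), in kcal * Angstrom / (mol * e^2).
COULOMB_KCAL_A = 332.0637

#: Boltzmann constant in kcal / (mol * K).
KB_KCAL_MOL_K = 0.0019872041

#: Avogadro-based conversion: 1 mol/L expressed as particles per Angstrom^3.
MOLAR_TO_PER_A3 = 6.02214076e-4

#: Zero Celsius in Kelvin.
T0_KELVIN = 273.15


def kbt_kcal_mol(temperature_celsius: float) -> float:
    """k_B T in kcal/mol at the given temperature (0.61633 at 37 C)."""
    return KB_KCAL_MOL_K * (T0_KELVIN + temperature_celsius)


def kcal_per_kbt(temperature_celsius: float) -> float:
    """Conversion factor: multiply an energy in k_B T to obtain kcal/mol."""
    return kbt_kcal_mol(temperature_celsius)


def bjerrum_vacuum_A(temperature_celsius: float) -> float:
    """Vacuum Bjerrum length e^2/(k_B T) in Angstrom (~539 A at 37 C).

    Dividing by a relative dielectric constant gives the usual Bjerrum
    length of the medium (~7 A in water at room temperature).
    """
    return COULOMB_KCAL_A / kbt_kcal_mol(temperature_celsius)
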