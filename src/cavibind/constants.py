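"""Physical constants and unit conventions.

Internal units throughout the package: kcal mol^-1 (energy), angstrom
(length), picosecond (time), kelvin (temperature), elementary charge.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 298.15

#: Coulomb prefactor so that q1*q2/r with q in e and r in angstrom gives kcal/mol.
COULOMB_CONSTANT = 332.0637

#: 1 kJ mol^-1 nm^-2 expressed in kcal mol^-1 A^-2.
KJ_NM2_TO_KCAL_A2 = 1.0 / 418.4

#: Volume per solute at 1 M standard concentration (A^3); C0 = 1/STANDARD_VOLUME.
STANDARD_VOLUME = 1661.0

#: Standard surface A0 = pi*r0^2 with r0 the radius of a sphere of volume 1661 A^3,
#: rounded to the conventional 170 A^2.
STANDARD_SURFACE = 170.0


def thermal_energy(temperature: float) -> float:
    """RT in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
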