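"""Physical constants and unit conventions.

Internal units: Angstrom, picosecond, Kelvin, kJ/mol.  A diffusivity of
0.1 A^2/ps equals exactly 1.0e-9 m^2/s, hence the conversion factor 10
between the two scales.
"""

#: Molar Boltzmann constant (gas constant) in kJ/(mol K).
KB_KJ_PER_MOL_K: float = 0.0083144626

#: Exact factor from A^2/ps to 1e-9 m^2/s.
D_A2_PS_TO_1E9_M2_S: float = 10.0

#: Standard laboratory temperature (K) at which k_B*T is ~2.48 kJ/mol.
STANDARD_TEMPERATURE_K: float = 298.15


def thermal_energy(temperature: float = STANDARD_TEMPERATURE_K) -> float:
    """Molar thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return KB_KJ_PER_MOL_K * temperature
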