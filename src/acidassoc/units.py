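"""Physical constants and unit conversions.

All energies inside the package are kJ/mol, lengths are angstroms (A),
concentrations are mM unless a function says otherwise.
"""

#: Gas constant, J/(mol K)
R_J = 8.314
#: Gas constant, kJ/(mol K)
R_KJ = R_J / 1000.0
#: Thermochemical calorie
KCAL_TO_KJ = 4.184
#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23


def kT(temperature: float) -> float:
    """Thermal energy in kJ/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ * temperature


def spring_kcal_to_kj(spring_kcal: float) -> float:
    """Convert a harmonic spring constant from kcal/(mol A^2) to kJ/(mol A^2)."""
    return spring_kcal * KCAL_TO_KJ


def reference_volume_molar(c0_molar: float = 1.0) -> float:
    """Volume per molecule (A^3) at standard concentration ``c0_molar`` (mol/L).

    For the 1 M standard state this is 1e27 / N_A ~ 1660.5 A^3.
    """
    if c0_molar <= 0:
        raise ValueError("standard concentration must be positive")
    return 1e27 / (c0_molar * N_AVOGADRO)
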