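"""Physical constants and unit conventions.

All pressures in the package are expressed in kPa, concentrations in
mol/L, molar volumes in cm^3/mol, and temperature in K.  The gas
constant R is in J/(mol K); the helper factors below absorb the unit
conversions so that model code never multiplies by powers of ten.
"""

R_J_PER_MOL_K: float = 8.314
"""Gas constant, J/(mol K)."""

T_DEFAULT_K: float = 298.15
"""Default temperature, K."""

WATER_MOLAR_VOLUME_CM3: float = 18.0
"""Molar volume of water, cm^3/mol."""


def rt_over_v1_kpa(temperature_k: float, solvent_molar_volume_cm3: float) -> float:
    """RT/V1 in kPa for V1 in cm^3/mol.

    R*T/V1 with V1 in cm^3/mol gives J/cm^3 = MPa; multiply by 1000 for kPa.
    """
    return 1000.0 * R_J_PER_MOL_K * temperature_k / solvent_molar_volume_cm3


def rt_kpa_per_molar(temperature_k: float) -> float:
    """RT in kPa per (mol/L): van 't Hoff factor for ideal osmotic pressure.

    R*T*c with c in mol/L gives J/L = kPa directly.
    """
    return R_J_PER_MOL_K * temperature_k


def nu_rt_kpa(crosslink_density_mol_cm3: float, temperature_k: float) -> float:
    """nu*RT in kPa for a cross-link (strand) density in mol/cm^3."""
    return 1000.0 * crosslink_density_mol_cm3 * R_J_PER_MOL_K * temperature_k
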