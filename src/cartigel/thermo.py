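"""Forward thermodynamic model of a single gel phase.

The swelling pressure of a gel is decomposed into three additive terms,

    Pi_sw(phi) = Pi_mix(phi) + Pi_ion(phi) - Pi_el(phi),

where phi is the polymer volume fraction (hydration = 1/phi):

* ``Pi_mix`` — Flory-Huggins osmotic pressure of polymer/solvent mixing,
  -(RT/V1) [ln(1-phi) + phi + chi phi^2]; the thermodynamic driving
  force of swelling.
* ``Pi_el``  — retractive elastic pressure of the cross-links, the ideal
  affine rubber-elasticity form nu RT phi_ref^(2/3) phi^(1/3); this is
  what prevents infinite swelling.
* ``Pi_ion`` — ideal Donnan excess osmotic pressure of mobile ions for
  polyelectrolyte networks, RT (sqrt(c_f^2 + 4 c_s^2) - 2 c_s), with the
  fixed-charge concentration c_f set by Henderson-Hasselbalch ionization
  of the chain's weak-acid groups; zero for neutral gels.

Free-swelling equilibrium is Pi_sw = 0; under an external osmotic stress
P the gel deswells to the composition where Pi_sw = P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import nu_rt_kpa, rt_kpa_per_molar, rt_over_v1_kpa
from .params import BathConditions, NeutralGelParams, PolyelectrolyteGelParams

__all__ = [
    "PressureDecomposition",
    "mixing_pressure",
    "elastic_pressure",
    "ionization_fraction",
    "fixed_charge_concentration",
    "ionic_pressure",
    "swelling_pressure",
    "swelling_pressure_only",
    "dpi_dphi",
    "osmotic_modulus_model",
    "equilibrium_volume_fraction",
    "equilibrium_hydration",
    "EquilibriumNotFoundError",
]

# Search bracket for equilibrium compositions (volume fraction).
PHI_BRACKET = (1e-4, 0.999)
PRESSURE_TOL_KPA = 1e-6


class EquilibriumNotFoundError(ValueError):
    """Raised when Pi_sw - P has no sign change on the search bracket."""


@dataclass(frozen=True)
class PressureDecomposition:
    """Pressure components (kPa) at one gel composition.

    Satisfies pi_sw = pi_mix + pi_ion - pi_el and hydration = 1/phi.
    """

    phi: float
    hydration: float
    pi_mix: float
    pi_el: float
    pi_ion: float
    pi_sw: float


def _check_phi(phi) -> None:
    phi = np.asarray(phi)
    if np.any(phi <= 0.0) or np.any(phi >= 1.0):
        raise ValueError(f"volume fraction must lie in (0, 1), got {phi}")


def mixing_pressure(
    phi: float, params: NeutralGelParams, bath: BathConditions
) -> float:
    """Flory-Huggins mixing pressure in kPa.

    Positive (swelling-promoting) for chi < 1/2 at small phi; the
    leading small-phi term is (RT/V1)(1/2 - chi) phi^2.
    """
    _check_phi(phi)
    a = rt_over_v1_kpa(bath.temperature, params.solvent_molar_volume)
    return -a * (np.log1p(-phi) + phi + params.chi * phi * phi)


def elastic_pressure(phi: float, params: NeutralGelParams) -> float:
    """Ideal affine elastic pressure nu RT phi_ref^(2/3) phi^(1/3), kPa.

    Temperature enters through nu RT; evaluated at the package default
    temperature unless a bath is threaded through ``swelling_pressure``.
    """
    return elastic_pressure_at(phi, params, None)


def elastic_pressure_at(
    phi: float, params: NeutralGelParams, bath: BathConditions | None
) -> float:
    _check_phi(phi)
    from .constants import T_DEFAULT_K

    t = bath.temperature if bath is not None else T_DEFAULT_K
    nurt = nu_rt_kpa(params.crosslink_density, t)
    return nurt * params.phi_ref ** (2.0 / 3.0) * phi ** (1.0 / 3.0)


def ionization_fraction(pH: float, pKa: float) -> float:
    """Henderson-Hasselbalch degree of dissociation of a weak acid."""
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def fixed_charge_concentration(
    phi: float, params: PolyelectrolyteGelParams, bath: BathConditions
) -> float:
    """Fixed-charge concentration inside the gel, mol/L.

    c_f = alpha * f_ionizable * f_effective * phi / v_monomer, with
    v_monomer in cm^3/mol (the factor 1000 converts mol/cm^3 to mol/L).
    """
    _check_phi(phi)
    alpha = ionization_fraction(bath.pH, params.pKa)
    return (
        1000.0
        * alpha
        * params.ionizable_fraction
        * params.effective_charge_fraction
        * phi
        / params.monomer_molar_volume
    )


def ionic_pressure(
    phi: float, params: PolyelectrolyteGelParams, bath: BathConditions
) -> float:
    """Ideal Donnan excess osmotic pressure, kPa.

    RT (sqrt(c_f^2 + 4 c_s^2) - 2 c_s) >= 0; reduces to the counterion
    ideal-gas limit RT c_f as the bath salt concentration c_s -> 0.
    """
    _check_phi(phi)
    cf = fixed_charge_concentration(phi, params, bath)
    cs = bath.salt_concentration
    return rt_kpa_per_molar(bath.temperature) * (
        np.hypot(cf, 2.0 * cs) - 2.0 * cs
    )


def swelling_pressure(
    phi: float, params: NeutralGelParams, bath: BathConditions
) -> PressureDecomposition:
    """Full pressure decomposition at composition phi.

    For neutral gels pi_ion is identically zero, so the identity reduces
    to pi_sw = pi_mix - pi_el.
    """
    _check_phi(phi)
    p_mix = mixing_pressure(phi, params, bath)
    p_el = elastic_pressure_at(phi, params, bath)
    if isinstance(params, PolyelectrolyteGelParams):
        p_ion = ionic_pressure(phi, params, bath)
    else:
        p_ion = 0.0
    return PressureDecomposition(
        phi=phi,
        hydration=1.0 / phi,
        pi_mix=p_mix,
        pi_el=p_el,
        pi_ion=p_ion,
        pi_sw=p_mix + p_ion - p_el,
    )


def swelling_pressure_only(phi, params: NeutralGelParams, bath: BathConditions):
    """pi_sw alone; array-safe cheap path for root finding and grids."""
    p = mixing_pressure(phi, params, bath) - elastic_pressure_at(phi, params, bath)
    if isinstance(params, PolyelectrolyteGelParams):
        p = p + ionic_pressure(phi, params, bath)
    return p


def dpi_dphi(phi: float, params: NeutralGelParams, bath: BathConditions) -> float:
    """Analytic derivative d(pi_sw)/d(phi) in kPa.

    d(Pi_mix)/dphi = (RT/V1) [phi/(1-phi) - 2 chi phi]
    d(Pi_el)/dphi  = Pi_el / (3 phi)
    d(Pi_ion)/dphi = RT c_f (dc_f/dphi) / sqrt(c_f^2 + 4 c_s^2)
    """
    _check_phi(phi)
    a = rt_over_v1_kpa(bath.temperature, params.solvent_molar_volume)
    d_mix = a * (phi / (1.0 - phi) - 2.0 * params.chi * phi)
    d_el = elastic_pressure_at(phi, params, bath) / (3.0 * phi)
    d_ion = 0.0
    if isinstance(params, PolyelectrolyteGelParams):
        cf = fixed_charge_concentration(phi, params, bath)
        cs = bath.salt_concentration
        if cf > 0.0:
            d_ion = (
                rt_kpa_per_molar(bath.temperature)
                * cf
                * (cf / phi)
                / np.hypot(cf, 2.0 * cs)
            )
    return d_mix + d_ion - d_el


def osmotic_modulus_model(
    phi: float, params: NeutralGelParams, bath: BathConditions
) -> float:
    """Osmotic compression modulus K_os = phi dPi/dphi (kPa), analytic."""
    return phi * dpi_dphi(phi, params, bath)


def solve_pressure_equilibrium(
    pressure_fn,
    external_pressure: float = 0.0,
    bracket: tuple[float, float] = PHI_BRACKET,
) -> float:
    """Root of pressure_fn(phi) = external_pressure on the stable branch.

    Scans a geometric grid for sign changes of the residual and polishes
    the largest-phi one with Brent's method.  The largest-phi crossing
    lies on the stable (dPi/dphi > 0) branch for every curve this
    package produces: pi_sw grows without bound as phi -> 1 through the
    mixing term and any spurious small-phi crossings sit below it.

    Raises
    ------
    EquilibriumNotFoundError
        If the residual has no sign change on the bracket (the stress is
        not attainable by this gel).
    """
    lo, hi = bracket

    def resid(phi: float) -> float:
        return pressure_fn(phi) - external_pressure

    grid = np.geomspace(lo, hi, 256)
    vals = np.asarray(resid(grid))  # pressure terms are array-safe
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] <= 0)[0]
    if len(idx) == 0:
        raise EquilibriumNotFoundError(
            f"no equilibrium in range: pressure never crosses "
            f"{external_pressure:g} kPa for phi in [{lo:g}, {hi:g}]"
        )
    i = idx[-1]
    phi_root = brentq(resid, grid[i], grid[i + 1], xtol=1e-15, rtol=1e-15)
    if abs(resid(phi_root)) > PRESSURE_TOL_KPA:
        raise EquilibriumNotFoundError(
            f"root polish failed: residual {resid(phi_root):g} kPa"
        )
    return float(phi_root)


def equilibrium_volume_fraction(
    params: NeutralGelParams,
    bath: BathConditions,
    external_pressure: float = 0.0,
    bracket: tuple[float, float] = PHI_BRACKET,
) -> float:
    """Composition at which pi_sw equals the external osmotic stress.

    external_pressure = 0 gives the free-swelling equilibrium of the
    gel; positive values describe osmotic deswelling (the returned phi
    increases monotonically with the applied stress).
    """
    return solve_pressure_equilibrium(
        lambda phi: swelling_pressure_only(phi, params, bath),
        external_pressure,
        bracket,
    )


def equilibrium_hydration(
    params: NeutralGelParams,
    bath: BathConditions,
    external_pressure: float = 0.0,
) -> float:
    """Equilibrium hydration 1/phi under an external osmotic stress."""
    return 1.0 / equilibrium_volume_fraction(params, bath, external_pressure)
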