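"""Curve-level analysis: equilibrium, prestress, modulus, Fung fit.

The central quantity is the prestress of a composite gel,

    P_el(h) = Pi_filler(h) - Pi_composite(h),   clamped at 0,

the tensile stress carried by the matrix because the encapsulated
filler swells against it.  P_el vanishes where the two swelling-pressure
curves intersect, increases with hydration, and reaches its maximum
P_el_max at the composite's free-swelling equilibrium (Pi_composite = 0),
where it equals the filler's remaining swelling pressure.  This is the
mirror image of the elastic pressure of an ordinary gel, which
*decreases* with hydration.

Load-bearing ability is quantified by the osmotic compression modulus
K_os = phi dPi/dphi, the resistance of the gel to a fractional volume
change under load.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, least_squares

from .curves import SwellingCurve



__all__ = [
    "PrestressCurve",
    "ModulusResult",
    "FungFit",
    "find_equilibrium",
    "find_intersection",
    "prestress_curve",
    "osmotic_modulus",
    "kos_ratio",
    "fit_fung",
    "NoZeroCrossingError",
    "NoPrestressError",
]


class NoZeroCrossingError(ValueError):
    """A required zero crossing does not exist on the curve."""


class NoPrestressError(ValueError):
    """The prestress is identically zero; there is nothing to fit."""


@dataclass(frozen=True)
class PrestressCurve:
    """Prestress P_el versus hydration for a composite gel.

    intersection_hydration  where P_el first becomes positive (None if
                            the curves never cross: no prestress).
    equilibrium_hydration   where the composite swelling pressure is 0.
    p_el_max                P_el at the equilibrium hydration, kPa.
    """

    hydration: np.ndarray
    p_el: np.ndarray
    intersection_hydration: Optional[float]
    equilibrium_hydration: Optional[float]
    p_el_max: Optional[float]

    def positive_points(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.p_el > 0.0
        return self.hydration[mask], self.p_el[mask]


@dataclass(frozen=True)
class ModulusResult:
    """Osmotic compression modulus at one composition."""

    phi: float
    hydration: float
    k_os: float  # kPa


@dataclass(frozen=True)
class FungFit:
    """Exponential (Fung-type) hyperelastic description of P_el(h).

    P_el(h) = amplitude * (exp(rate * (h - onset_hydration)) - 1)
    for h >= onset_hydration, zero below.
    """

    amplitude: float  # kPa
    rate: float  # per hydration unit
    onset_hydration: float
    rmse: float  # kPa

    def predict(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        out = self.amplitude * np.expm1(
            self.rate * (h - self.onset_hydration)
        )
        return np.where(h >= self.onset_hydration, out, 0.0)


# ----------------------------------------------------------------------


def _zero_crossings(fn, lo: float, hi: float, n: int = 2048) -> list[float]:
    """All roots of a scalar function on [lo, hi], bisection-refined."""
    grid = np.linspace(lo, hi, n)
    vals = np.asarray(fn(grid), dtype=float)
    # values negligibly small on the curve's pressure scale count as
    # zeros (interpolants do not return exact 0.0 at data knots)
    tol = 1e-12 * max(1.0, float(np.nanmax(np.abs(vals))))
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if abs(a) <= tol:
            roots.append(float(grid[i]))
        elif a * b < 0.0:
            roots.append(
                float(brentq(lambda x: float(fn(x)), grid[i], grid[i + 1],
                             xtol=1e-13))
            )
    if abs(vals[-1]) <= tol:
        roots.append(float(grid[-1]))
    # deduplicate near-coincident roots from grid nodes
    out: list[float] = []
    for r in roots:
        if not out or abs(r - out[-1]) > 1e-10 * max(1.0, abs(r)):
            out.append(r)
    return out


def find_equilibrium(curve: SwellingCurve) -> float:
    """Hydration at which the interpolated swelling pressure is zero.

    Raises
    ------
    NoZeroCrossingError
        If the curve's pressure never reaches zero in range — the
        equilibrium would require extrapolation, which is refused.
    """
    interp = curve.interpolant()
    roots = _zero_crossings(interp, curve.hmin, curve.hmax)
    if not roots:
        raise NoZeroCrossingError(
            f"curve '{curve.label}': swelling pressure has no zero "
            f"crossing in [{curve.hmin:g}, {curve.hmax:g}]"
        )
    # monotone-decreasing curves have a unique root; take the largest to
    # be robust to flat numerical plateaus
    return roots[-1]


def find_intersection(
    composite: SwellingCurve, filler: SwellingCurve
) -> Optional[float]:
    """Hydration where the filler and composite curves cross.

    Returns None if the curves never cross on their shared range (no
    prestress is generated).  If several crossings exist, the
    largest-hydration crossing below the composite's equilibrium
    hydration is returned (below the largest crossing when the
    equilibrium is outside the shared range).
    """
    lo, hi = composite.overlap(filler)
    fi = filler.interpolant()
    ci = composite.interpolant()
    roots = _zero_crossings(lambda h: fi(h) - ci(h), lo, hi)
    if not roots:
        return None
    try:
        h_eq = find_equilibrium(composite)
    except NoZeroCrossingError:
        h_eq = None
    if h_eq is not None:
        below = [r for r in roots if r <= h_eq]
        if below:
            return below[-1]
    return roots[-1]


def prestress_curve(
    filler: SwellingCurve, composite: SwellingCurve
) -> PrestressCurve:
    """Prestress P_el(h) = max(0, Pi_filler - Pi_composite) on the
    shared hydration grid.

    The grid is the union of both curves' sample points restricted to
    the overlapping range, so no input information is discarded.
    """
    lo, hi = composite.overlap(filler)
    h = np.union1d(filler.hydration, composite.hydration)
    h = h[(h >= lo) & (h <= hi)]
    fi = filler.interpolant()
    ci = composite.interpolant()
    p_el = np.maximum(0.0, fi(h) - ci(h))

    intersection = find_intersection(composite, filler)
    try:
        h_eq = find_equilibrium(composite)
    except NoZeroCrossingError:
        h_eq = None
    p_el_max: Optional[float] = None
    if h_eq is not None and lo <= h_eq <= hi:
        p_el_max = float(max(0.0, fi(h_eq) - ci(h_eq)))
    return PrestressCurve(
        hydration=h,
        p_el=p_el,
        intersection_hydration=intersection,
        equilibrium_hydration=h_eq,
        p_el_max=p_el_max,
    )


def osmotic_modulus(
    source,
    phi: float,
    bath=None,
) -> ModulusResult:
    """Osmotic compression modulus K_os = phi dPi/dphi at composition phi.

    ``source`` may be a :class:`SwellingCurve` (centered finite
    difference on the monotone interpolant, in hydration coordinates:
    K_os = -h dPi/dh) or a gel/composite parameter object together with
    ``bath`` (analytic derivative).
    """
    if isinstance(source, SwellingCurve):
        h = 1.0 / phi
        if not (source.hmin < h < source.hmax):
            raise ValueError(
                f"phi={phi:g} (hydration {h:g}) is at or outside the "
                f"curve range [{source.hmin:g}, {source.hmax:g}]"
            )
        interp = source.interpolant()
        # centered difference with a step small vs. curvature scale but
        # large vs. interpolation noise
        dh = 1e-4 * (source.hmax - source.hmin)
        dh = min(dh, (source.hmax - h) / 2, (h - source.hmin) / 2)
        dpi_dh = (interp(h + dh) - interp(h - dh)) / (2.0 * dh)
        k_os = float(-h * dpi_dh)
        return ModulusResult(phi=phi, hydration=h, k_os=k_os)

    from .composite import composite_dpi_dphi
    from .params import CompositeParams
    from .thermo import dpi_dphi

    if bath is None:
        raise ValueError("bath conditions required for model-based K_os")
    if isinstance(source, CompositeParams):
        deriv = composite_dpi_dphi(phi, source, bath)
    else:
        deriv = dpi_dphi(phi, source, bath)
    return ModulusResult(phi=phi, hydration=1.0 / phi, k_os=float(phi * deriv))


def kos_ratio(
    curve_a: SwellingCurve, curve_b: SwellingCurve, hydration: float
) -> float:
    """K_os(a) / K_os(b) at a common hydration."""
    phi = 1.0 / hydration
    ka = osmotic_modulus(curve_a, phi).k_os
    kb = osmotic_modulus(curve_b, phi).k_os
    if kb == 0.0:
        raise ZeroDivisionError(
            f"K_os of curve '{curve_b.label}' is zero at hydration "
            f"{hydration:g}"
        )
    return ka / kb


# ----------------------------------------------------------------------
# Fung fit


def fit_fung(prestress: PrestressCurve) -> FungFit:
    """Least-squares fit of the exponential Fung form to P_el(h).

    Initialization is deterministic: the onset h0 starts at the
    intersection hydration (or the last zero-prestress point), and A, b
    come from a log-linear regression of log P_el on h - h0.  The three
    parameters are then refined jointly with bounded least squares.

    Raises
    ------
    NoPrestressError
        If the prestress is identically zero.
    ValueError
        If fewer than four points carry positive prestress.
    """
    h_pos, p_pos = prestress.positive_points()
    if len(h_pos) == 0:
        raise NoPrestressError("prestress is identically zero; nothing to fit")
    if len(h_pos) < 4:
        raise ValueError(
            f"need at least 4 points with positive prestress, got {len(h_pos)}"
        )

    if prestress.intersection_hydration is not None:
        h0_init = prestress.intersection_hydration
    else:
        below = prestress.hydration[prestress.hydration < h_pos[0]]
        h0_init = float(below[-1]) if len(below) else float(h_pos[0]) - 1e-6
    h0_init = min(h0_init, float(h_pos[0]) - 1e-9)

    # log-linear pre-fit: log P ~ log A + b (h - h0) for b(h-h0) >~ 1
    x = h_pos - h0_init
    coef = np.polyfit(x, np.log(p_pos), 1)
    b_init = max(float(coef[0]), 1e-6)
    a_init = max(float(np.exp(coef[1])), 1e-12)

    def resid(theta: np.ndarray) -> np.ndarray:
        a, b, h0 = theta
        return a * np.expm1(b * (h_pos - h0)) - p_pos

    h0_hi = float(h_pos[0]) - 1e-12
    h0_lo = h0_hi - 10.0 * (float(h_pos[-1]) - float(h_pos[0]) + 1.0)
    sol = least_squares(
        resid,
        x0=[a_init, b_init, min(h0_init, h0_hi)],
        bounds=([1e-15, 1e-9, h0_lo], [np.inf, np.inf, h0_hi]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    a, b, h0 = map(float, sol.x)
    rmse = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return FungFit(amplitude=a, rate=b, onset_hydration=h0, rmse=rmse)
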