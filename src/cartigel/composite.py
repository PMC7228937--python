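"""Two-phase composite gel: matrix + encapsulated polyelectrolyte filler.

The composite swelling pressure at a shared composition is the
volume-weighted (isostrain) combination of the phase pressures,

    Pi_comp(phi) = x_f Pi_filler(phi) + (1 - x_f) Pi_matrix(phi),

where x_f is the filler share of the total polymer.  Both phases are
evaluated at the same overall volume fraction: the analysis layer
operates on curves and is agnostic to how they were generated, and this
simplest closure reproduces every qualitative feature of the measured
systems once the presets are calibrated (filler swelling greater than
matrix swelling at high pH, curve intersection, stiffening).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .curves import CurveValidationError, SwellingCurve
from .params import (
    BathConditions,
    CompositeParams,
    NeutralGelParams,
    PolyelectrolyteGelParams,
)
from .thermo import dpi_dphi, swelling_pressure_only

__all__ = [
    "composite_swelling_pressure",
    "composite_dpi_dphi",
    "composite_curves",
    "composite_equilibrium_volume_fraction",
    "phase_stresses",
    "default_presets",
    "matrix_preset",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = (
    "pva1",
    "pva2",
    "composite_ph7",
    "composite_ph4",
    "composite_ph1",
    "cartilage_healthy",
    "cartilage_oa",
)


def composite_swelling_pressure(
    phi: float, comp: CompositeParams, bath: BathConditions
) -> float:
    """Composite pi_sw (kPa) at overall polymer volume fraction phi."""
    x = comp.filler_polymer_fraction
    pf = swelling_pressure_only(phi, comp.filler, bath)
    pm = swelling_pressure_only(phi, comp.matrix, bath)
    return x * pf + (1.0 - x) * pm


def composite_dpi_dphi(
    phi: float, comp: CompositeParams, bath: BathConditions
) -> float:
    """Analytic d(pi_sw)/dphi of the composite (kPa)."""
    x = comp.filler_polymer_fraction
    return x * dpi_dphi(phi, comp.filler, bath) + (1.0 - x) * dpi_dphi(
        phi, comp.matrix, bath
    )


def composite_equilibrium_volume_fraction(
    comp: CompositeParams, bath: BathConditions, external_pressure: float = 0.0
) -> float:
    """Composition where the composite pi_sw equals the external stress."""
    from .thermo import solve_pressure_equilibrium

    return solve_pressure_equilibrium(
        lambda phi: composite_swelling_pressure(phi, comp, bath),
        external_pressure,
    )


def phase_stresses(
    comp: CompositeParams, bath: BathConditions
) -> dict[str, float]:
    """Volume-weighted phase stresses of the unloaded composite, kPa.

    At free-swelling equilibrium the filler's positive swelling pressure
    (it is under compression by the matrix) is balanced by the matrix's
    negative swelling pressure (the matrix is inflated, i.e. in
    tension); their weighted sum — the net stress — is zero.
    """
    x = comp.filler_polymer_fraction
    phi_eq = composite_equilibrium_volume_fraction(comp, bath)
    pf = swelling_pressure_only(phi_eq, comp.filler, bath)
    pm = swelling_pressure_only(phi_eq, comp.matrix, bath)
    return {
        "phi_eq": phi_eq,
        "hydration_eq": 1.0 / phi_eq,
        "filler_stress_kpa": x * pf,
        "matrix_stress_kpa": (1.0 - x) * pm,
        "net_stress_kpa": x * pf + (1.0 - x) * pm,
    }


def composite_curves(
    comp: CompositeParams,
    bath: BathConditions,
    hydration_grid: np.ndarray,
) -> tuple[SwellingCurve, SwellingCurve]:
    """Composite and encapsulated-filler swelling-pressure curves.

    Returns (composite, filler) evaluated on the same hydration grid.
    The filler curve is the filler phase alone at the shared
    composition: the pressure it would exert were it not restrained.
    """
    h = np.asarray(hydration_grid, dtype=float)
    if h.ndim != 1 or len(h) < 2 or np.any(np.diff(h) <= 0):
        raise ValueError("hydration_grid must be 1-D and strictly increasing")
    phi = 1.0 / h
    x = comp.filler_polymer_fraction
    pf = np.asarray(swelling_pressure_only(phi, comp.filler, bath))
    pm = np.asarray(swelling_pressure_only(phi, comp.matrix, bath))
    pc = x * pf + (1.0 - x) * pm
    if np.any(np.diff(pc) >= 0):
        raise CurveValidationError(
            "composite pressure curve is not strictly decreasing in "
            "hydration on the requested grid; the preset is miscalibrated"
        )
    comp_curve = SwellingCurve(
        hydration=h, pressure=pc, label=(comp.label or "composite"), bath=bath
    )
    filler_curve = SwellingCurve(
        hydration=h,
        pressure=pf,
        label=f"{comp.label or 'composite'}:filler",
        bath=bath,
        strict=False,  # the filler alone need not be monotone over the grid
    )
    return comp_curve, filler_curve


# ----------------------------------------------------------------------
# presets


def _preset_text(name: str) -> str:
    ref = resources.files("cartigel").joinpath(f"presets/{name}.yaml")
    return ref.read_text(encoding="utf-8")


def load_preset(name: str) -> dict:
    """Raw preset mapping from the packaged configuration file."""
    if name not in PRESET_NAMES:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    return yaml.safe_load(_preset_text(name))


def _bath_from(d: dict) -> BathConditions:
    return BathConditions(**d["bath"])


def matrix_preset(name: str) -> tuple[NeutralGelParams, BathConditions]:
    """Single-phase matrix presets: 'pva1' (denser) or 'pva2' (looser)."""
    d = load_preset(name)
    if "matrix" in d and "filler" not in d:
        return NeutralGelParams(**d["matrix"]), _bath_from(d)
    raise ValueError(f"preset {name!r} is not a single-phase matrix preset")


def default_presets(ph_case: int) -> tuple[CompositeParams, BathConditions]:
    """Calibrated composite presets for bath pH 7, 4 or 1.

    All use 0.1 mol/L salt.  The filler's weak-acid groups are fully
    dissociated at pH 7, partly at pH 4 and essentially protonated at
    pH 1, so the filler equilibrium swelling is ordered 7 > 4 > 1 and at
    pH 1 the composite develops no prestress.
    """
    if ph_case not in (7, 4, 1):
        raise ValueError(f"ph_case must be 7, 4 or 1, got {ph_case!r}")
    d = load_preset(f"composite_ph{ph_case}")
    comp = CompositeParams(
        matrix=NeutralGelParams(**d["matrix"]),
        filler=PolyelectrolyteGelParams(**d["filler"]),
        filler_polymer_fraction=d.get("filler_polymer_fraction", 0.5),
        label=d.get("label", f"composite_ph{ph_case}"),
    )
    return comp, _bath_from(d)
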