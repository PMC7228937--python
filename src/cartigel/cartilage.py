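"""Cartilage as a composite gel: healthy vs osteoarthritic presets.

Articular cartilage is modelled with the same two-phase machinery as a
synthetic composite gel: a neutral, relatively stiff matrix stands in
for the collagen network and a charged filler for the proteoglycan
(aggrecan) phase whose Donnan pressure inflates it.  The decomposition
of the tissue swelling curve into the proteoglycan osmotic pressure
Pi_PG and the collagen tensile stress P_COLL is numerically identical
to the gel prestress decomposition (filler -> PG, composite -> tissue)
and shares that code path.

The tissue hydration axis V_total/V_C (total tissue volume per collagen
volume) is treated as the same abstract coordinate as the gel's 1/phi;
no conversion factor is applied.  Presets are synthetic analogs
constrained by qualitative pathology: the osteoarthritic (OA) collagen
network is weaker, so the OA curve is less steep (smaller K_os) and
displaced to higher hydration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .analysis import PrestressCurve, prestress_curve

from .composite import (
    composite_curves,
    composite_equilibrium_volume_fraction,
    load_preset,
)
from .curves import SwellingCurve
from .params import (
    BathConditions,
    CompositeParams,
    NeutralGelParams,
    PolyelectrolyteGelParams,
)

__all__ = [
    "CartilageDecomposition",
    "decompose_cartilage",
    "tissue_presets",
    "tissue_curves",
    "compare_curves",
    "CurveComparison",
]


@dataclass(frozen=True)
class CartilageDecomposition:
    """Pi_PG / P_COLL decomposition of a tissue swelling curve.

    collagen_tension is P_COLL = Pi_PG - Pi_sw clamped at zero; at the
    equilibrium hydration it equals the full proteoglycan pressure.
    """

    hydration: np.ndarray
    pg_pressure: np.ndarray
    collagen_tension: np.ndarray
    equilibrium_hydration: float | None
    prestress: PrestressCurve


def decompose_cartilage(
    swelling: SwellingCurve, pg: SwellingCurve
) -> CartilageDecomposition:
    """Split a tissue swelling curve into PG pressure and collagen tension.

    Delegates to the gel prestress analysis (single code path); emits a
    warning when the tissue curve lies above the PG curve everywhere,
    which clamps the collagen tension to zero.
    """
    pre = prestress_curve(filler=pg, composite=swelling)
    if not np.any(pre.p_el > 0.0):
        warnings.warn(
            f"tissue curve '{swelling.label}' lies above the PG curve "
            f"'{pg.label}' over the whole shared range: collagen tension "
            "is identically zero",
            stacklevel=2,
        )
    pg_on_grid = pg.interpolant()(pre.hydration)
    return CartilageDecomposition(
        hydration=pre.hydration,
        pg_pressure=pg_on_grid,
        collagen_tension=pre.p_el,
        equilibrium_hydration=pre.equilibrium_hydration,
        prestress=pre,
    )


def tissue_presets(state: str) -> tuple[CompositeParams, BathConditions]:
    """Calibrated cartilage analog, 'healthy' or 'OA'.

    The healthy preset has a stiffer collagen matrix (higher effective
    cross-link density) than the OA preset; everything else matches, so
    preset differences isolate collagen weakening.
    """
    key = state.lower()
    if key == "oa":
        name = "cartilage_oa"
    elif key == "healthy":
        name = "cartilage_healthy"
    else:
        raise ValueError(f"tissue state must be 'healthy' or 'OA', got {state!r}")
    d = load_preset(name)
    comp = CompositeParams(
        matrix=NeutralGelParams(**d["matrix"]),
        filler=PolyelectrolyteGelParams(**d["filler"]),
        filler_polymer_fraction=d.get("filler_polymer_fraction", 0.5),
        label=d.get("label", name),
    )
    return comp, BathConditions(**d["bath"])


def tissue_curves(
    state: str, hydration_grid: np.ndarray | None = None
) -> tuple[SwellingCurve, SwellingCurve]:
    """(tissue swelling curve, PG pressure curve) for a tissue preset.

    The default grid spans from well below to slightly above the
    preset's equilibrium hydration.
    """
    comp, bath = tissue_presets(state)
    if hydration_grid is None:
        h_eq = 1.0 / composite_equilibrium_volume_fraction(comp, bath)
        hydration_grid = np.linspace(0.3 * h_eq, 1.15 * h_eq, 160)
    tissue, pg = composite_curves(comp, bath, hydration_grid)
    ts = "OA" if state.lower() == "oa" else "healthy"
    tissue = SwellingCurve(
        hydration=tissue.hydration, pressure=tissue.pressure,
        label=tissue.label, bath=bath, tissue_state=ts,
    )
    pg = SwellingCurve(
        hydration=pg.hydration, pressure=pg.pressure,
        label=pg.label, bath=bath, tissue_state=ts, strict=False,
    )
    return tissue, pg


# ----------------------------------------------------------------------
# curve comparison


@dataclass(frozen=True)
class CurveComparison:
    """Similarity report between two swelling curves."""

    rmse_kpa: float
    equilibrium_hydration_a: float | None
    equilibrium_hydration_b: float | None
    equilibrium_shift: float | None
    kos_ratio: float | None
    overlap: tuple[float, float]


def compare_curves(a: SwellingCurve, b: SwellingCurve,
                   n_grid: int = 512) -> CurveComparison:
    """Compare two curves on their shared hydration range.

    Reports the RMS pressure difference on a common grid, the
    difference of equilibrium hydrations (a - b, when both exist), and
    the K_os ratio a/b at the midpoint of the two equilibria (falling
    back to the centre of the overlap when either equilibrium is
    missing or out of range).
    """
    from .analysis import NoZeroCrossingError, find_equilibrium, kos_ratio

    lo, hi = a.overlap(b)
    grid = np.linspace(lo, hi, n_grid)
    pa = a.interpolant()(grid)
    pb = b.interpolant()(grid)
    rmse = float(np.sqrt(np.mean((pa - pb) ** 2)))

    def _eq(c: SwellingCurve) -> float | None:
        try:
            return find_equilibrium(c)
        except NoZeroCrossingError:
            return None

    ea, eb = _eq(a), _eq(b)
    shift = (ea - eb) if (ea is not None and eb is not None) else None

    if ea is not None and eb is not None:
        h_ref = 0.5 * (ea + eb)
    else:
        h_ref = 0.5 * (lo + hi)
    h_ref = min(max(h_ref, lo * 1.001), hi * 0.999)
    try:
        kr = kos_ratio(a, b, h_ref)
    except (ValueError, ZeroDivisionError):
        kr = None
    return CurveComparison(
        rmse_kpa=rmse,
        equilibrium_hydration_a=ea,
        equilibrium_hydration_b=eb,
        equilibrium_shift=shift,
        kos_ratio=kr,
        overlap=(lo, hi),
    )
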