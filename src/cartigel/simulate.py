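"""Synthetic osmotic-stress experiments and parameter recovery.

The osmotic stress (dialysis) technique equilibrates a gel against
polymer solutions of known osmotic pressure and measures the gel
concentration reached at equilibrium.  The simulator reproduces that
structure: the stressing pressures are exact (they are set by the
experimenter), the measured quantity is the gel composition, and the
measurement error is multiplicative on hydration — a mean-one lognormal
with a chosen coefficient of variation, which keeps hydration positive.

All randomness flows from a single integer seed through
``numpy.random.Philox`` (counter-based), so regenerating a fixture with
the same seed is bit-identical across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .composite import composite_equilibrium_volume_fraction
from .curves import SwellingCurve
from .params import (
    BathConditions,
    CompositeParams,
    ExperimentDesign,
    NeutralGelParams,
    PolyelectrolyteGelParams,
)
from .thermo import (
    EquilibriumNotFoundError,
    equilibrium_volume_fraction,
)

__all__ = [
    "RecoveryResult",
    "default_design",
    "fixture_design",
    "simulate_osmotic_stress",
    "recover_parameters",
    "generate_fixture_suite",
    "FIXTURE_NAMES",
]


DEFAULT_STRESS_LADDER = tuple(np.geomspace(0.5, 500.0, 12))
"""12 stressing pressures, log-spaced over 0.5-500 kPa: spans the
nonlinear region of the default presets."""


def default_design(seed: int = 0, noise_cv: float = 0.02,
                   replicates: int = 1) -> ExperimentDesign:
    return ExperimentDesign(
        stress_ladder=list(DEFAULT_STRESS_LADDER),
        noise_cv=noise_cv,
        replicates=replicates,
        seed=seed,
    )


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of fitting gel parameters to a measured curve."""

    true_params: Optional[NeutralGelParams]
    estimated_params: NeutralGelParams
    relative_errors: dict[str, float]
    converged: bool
    cost: float


def simulate_osmotic_stress(
    params,
    bath: BathConditions,
    design: ExperimentDesign,
) -> SwellingCurve:
    """Simulate one osmotic-stress experiment -> noisy swelling curve.

    For each stressing pressure the equilibrium composition is solved
    from the forward model; the corresponding hydration then receives
    multiplicative lognormal noise with coefficient of variation
    ``design.noise_cv``.  Points are sorted by hydration.  The returned
    curve is non-strict: measurement noise can locally upset pressure
    monotonicity.

    Raises
    ------
    EquilibriumNotFoundError
        Naming the first stress level the model cannot attain.
    """
    if isinstance(params, CompositeParams):
        solve = lambda p: composite_equilibrium_volume_fraction(params, bath, p)
    else:
        solve = lambda p: equilibrium_volume_fraction(params, bath, p)

    hydr_true = []
    for level in design.stress_ladder:
        try:
            phi = solve(level)
        except EquilibriumNotFoundError as err:
            raise EquilibriumNotFoundError(
                f"stress level {level:g} kPa is not attainable: {err}"
            ) from err
        hydr_true.append(1.0 / phi)

    rng = _rng(design.seed)
    h_pts, p_pts = [], []
    cv = design.noise_cv
    sigma = np.sqrt(np.log1p(cv * cv))
    for level, h in zip(design.stress_ladder, hydr_true):
        for _ in range(design.replicates):
            if sigma > 0.0:
                noise = np.exp(sigma * rng.standard_normal() - 0.5 * sigma**2)
            else:
                noise = 1.0
            h_pts.append(h * noise)
            p_pts.append(level)

    order = np.argsort(h_pts)[::-1]  # high stress = low hydration first
    h_arr = np.asarray(h_pts)[order][::-1]
    p_arr = np.asarray(p_pts)[order][::-1]
    # break exact hydration ties (possible only at cv=0 with replicates)
    for i in range(1, len(h_arr)):
        if h_arr[i] <= h_arr[i - 1]:
            h_arr[i] = np.nextafter(h_arr[i - 1], np.inf)

    label = getattr(params, "label", "") or "simulated"
    return SwellingCurve(
        hydration=h_arr,
        pressure=p_arr,
        label=f"{label} (osmotic stress, cv={cv:g})",
        bath=bath,
        seed=design.seed,
        strict=False,
    )


# ----------------------------------------------------------------------
# parameter recovery


_NEUTRAL_FREE = ("chi", "crosslink_density")
_CHARGED_FREE = ("chi", "crosslink_density", "pKa", "effective_charge_fraction")


def recover_parameters(
    curve: SwellingCurve,
    model_family: str,
    init: NeutralGelParams,
    bounds: dict[str, tuple[float, float]],
    bath: Optional[BathConditions] = None,
    true_params: Optional[NeutralGelParams] = None,
) -> RecoveryResult:
    """Fit gel parameters to a measured osmotic-stress curve.

    The stressing pressures are exact and the noise sits on hydration,
    so the residual is taken on log hydration: for each measured
    pressure the model's equilibrium hydration is solved and compared
    with the measured one.  Free parameters are chi and the cross-link
    density (plus pKa and the effective charge fraction for
    polyelectrolytes); the remaining fields are held at their ``init``
    values.  Deterministic given the data and ``init``.

    Parameters are fitted on a log scale for chi-independent scaling of
    the cross-link density.
    """
    if model_family not in ("neutral", "polyelectrolyte"):
        raise ValueError(f"unknown model family {model_family!r}")
    if len(curve.hydration) < 6:
        raise ValueError("need at least 6 points to fit gel parameters")
    bath = bath or curve.bath
    if bath is None:
        raise ValueError("bath conditions required (curve has none attached)")

    free = _NEUTRAL_FREE if model_family == "neutral" else _CHARGED_FREE
    for name in free:
        if name not in bounds:
            raise ValueError(f"missing bounds for free parameter {name!r}")
        lo, hi = bounds[name]
        v = getattr(init, name)
        if not (lo <= v <= hi):
            raise ValueError(
                f"init value {name}={v:g} outside bounds [{lo:g}, {hi:g}]"
            )

    base = init.model_dump()

    def build(theta: np.ndarray) -> NeutralGelParams:
        d = dict(base)
        for name, val in zip(free, theta):
            d[name] = float(val)
        cls = (
            NeutralGelParams
            if model_family == "neutral"
            else PolyelectrolyteGelParams
        )
        return cls(**d)

    h_obs = curve.hydration
    p_obs = curve.pressure

    def resid(theta: np.ndarray) -> np.ndarray:
        params = build(theta)
        out = np.empty_like(h_obs)
        for i, (h, p) in enumerate(zip(h_obs, p_obs)):
            try:
                phi = equilibrium_volume_fraction(params, bath, p)
                out[i] = np.log(h * phi)  # log(h_obs) - log(h_model)
            except EquilibriumNotFoundError:
                out[i] = 10.0  # strong penalty, keeps the solver in range
        return out

    x0 = np.array([getattr(init, n) for n in free])
    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])
    sol = least_squares(
        resid, x0=x0, bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    est = build(sol.x)
    converged = bool(sol.success)

    rel: dict[str, float] = {}
    if true_params is not None:
        for name in free:
            t = getattr(true_params, name, None)
            if t is not None and t != 0:
                rel[name] = abs(getattr(est, name) - t) / abs(t)
    return RecoveryResult(
        true_params=true_params,
        estimated_params=est,
        relative_errors=rel,
        converged=converged,
        cost=float(sol.cost),
    )


# ----------------------------------------------------------------------
# fixture suite

FIXTURE_NAMES = (
    "pva1",
    "pva2",
    "composite_ph7",
    "filler_ph7",
    "composite_ph4",
    "filler_ph4",
    "composite_ph1",
    "filler_ph1",
    "cartilage_healthy",
    "cartilage_oa",
)
"""The ten documented fixture curves: two single matrices of different
cross-link density, composite + encapsulated-filler pairs at bath pH
7/4/1, and healthy/OA cartilage analogs."""

FIXTURE_NOISE_CV = 0.005
FIXTURE_STRESS_LADDER = (0.0,) + tuple(np.geomspace(20.0, 500.0, 12))
"""Fixture measurements: one free-swelling specimen (zero stress, which
anchors the equilibrium hydration) plus twelve stressed levels over the
steep part of the curve.  Between 0 and 20 kPa the pressure-hydration
relation is almost flat, so composition noise at intermediate rungs
there would scramble the pressure ordering of neighbouring points."""


def fixture_design(seed: int) -> ExperimentDesign:
    return ExperimentDesign(
        stress_ladder=list(FIXTURE_STRESS_LADDER),
        noise_cv=FIXTURE_NOISE_CV,
        replicates=1,
        seed=seed,
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n sub-seeds (< 2^31) from one master seed, counter-based."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def generate_fixture_suite(seed: int, out_dir=None) -> dict[str, SwellingCurve]:
    """Generate the full named bundle of test-fixture curves.

    Matrix and composite curves are simulated osmotic-stress
    measurements (noisy); the encapsulated-filler curves are forward
    model evaluations on a fixed hydration grid (they are not directly
    measurable).  Cartilage analogs are simulated tissue measurements
    from the healthy/OA presets.  With ``out_dir`` set, one curve file
    per system plus a ``manifest.yaml`` recording the seed and all
    parameters are written; regeneration with the same seed is
    byte-identical.
    """
    from pathlib import Path

    import yaml

    from .cartilage import tissue_presets
    from .composite import (
        composite_curves,
        composite_equilibrium_volume_fraction,
        default_presets,
        matrix_preset,
    )
    from .io import write_curve

    seeds = _child_seeds(seed, len(FIXTURE_NAMES))
    curves: dict[str, SwellingCurve] = {}
    manifest: dict = {"seed": seed, "noise_cv": FIXTURE_NOISE_CV,
                      "curves": {}}

    def _record(name: str, curve: SwellingCurve, params_dump: dict) -> None:
        curves[name] = curve
        manifest["curves"][name] = {
            "label": curve.label,
            "n_points": int(len(curve.hydration)),
            "parameters": params_dump,
        }

    # single matrices
    for i, name in enumerate(("pva1", "pva2")):
        params, bath = matrix_preset(name)
        design = fixture_design(seeds[i])
        curve = simulate_osmotic_stress(params, bath, design)
        curve = SwellingCurve(
            hydration=curve.hydration, pressure=curve.pressure,
            label=name, bath=bath, seed=design.seed, strict=curve.strict,
        )
        _record(name, curve, params.model_dump())

    # composite + filler pairs
    for j, ph in enumerate((7, 4, 1)):
        comp, bath = default_presets(ph)
        design = fixture_design(seeds[2 + 2 * j])
        meas = simulate_osmotic_stress(comp, bath, design)
        meas = SwellingCurve(
            hydration=meas.hydration, pressure=meas.pressure,
            label=f"composite_ph{ph}", bath=bath, seed=design.seed,
            strict=meas.strict,
        )
        _record(f"composite_ph{ph}", meas, {
            "matrix": comp.matrix.model_dump(),
            "filler": comp.filler.model_dump(),
            "filler_polymer_fraction": comp.filler_polymer_fraction,
        })
        phi_eq = composite_equilibrium_volume_fraction(comp, bath)
        grid = np.linspace(meas.hmin, 1.15 / phi_eq, 120)
        _, filler = composite_curves(comp, bath, grid)
        filler = SwellingCurve(
            hydration=filler.hydration, pressure=filler.pressure,
            label=f"filler_ph{ph}", bath=bath, strict=False,
        )
        _record(f"filler_ph{ph}", filler, comp.filler.model_dump())

    # cartilage analogs
    for k, state in enumerate(("healthy", "oa")):
        comp, bath = tissue_presets(state)
        design = fixture_design(seeds[8 + k])
        meas = simulate_osmotic_stress(comp, bath, design)
        meas = SwellingCurve(
            hydration=meas.hydration, pressure=meas.pressure,
            label=f"cartilage_{state}", bath=bath, seed=design.seed,
            tissue_state="OA" if state == "oa" else "healthy",
            strict=meas.strict,
        )
        _record(f"cartilage_{state}", meas, {
            "matrix": comp.matrix.model_dump(),
            "filler": comp.filler.model_dump(),
            "filler_polymer_fraction": comp.filler_polymer_fraction,
        })

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, curve in curves.items():
            write_curve(curve, out / f"{name}.csv")
        manifest["creation_command"] = (
            f"cartigel simulate --fixtures --seed {seed}"
        )
        with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return curves
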