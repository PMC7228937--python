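"""Swelling-pressure curves: the universal exchange object.

A :class:`SwellingCurve` is an ordered set of (hydration, pressure)
points with bath metadata.  Hydration is 1/phi for gels and, for
cartilage, total tissue volume per collagen volume — the two are treated
as the same abstract coordinate.  Analysis code interpolates curves with
a monotone shape-preserving cubic (PCHIP), which keeps zero crossings of
these strongly nonlinear but monotone curves unique.
"""

from __future__ import annotations


from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .params import BathConditions

__all__ = ["SwellingCurve", "CurveValidationError"]


class CurveValidationError(ValueError):
    """A curve violates the ordering/monotonicity contract."""


@dataclass(frozen=True)
class SwellingCurve:
    """Ordered (hydration, pressure kPa) points plus metadata.

    ``strict=True`` (the default for analysis inputs) enforces strictly
    increasing hydration >= 1 and strictly decreasing pressure.  Noisy
    simulated measurements may legitimately violate the pressure
    monotonicity, so generators construct curves with ``strict=False``;
    hydration ordering is always enforced.
    """

    hydration: np.ndarray
    pressure: np.ndarray
    label: str = ""
    bath: Optional[BathConditions] = None
    tissue_state: Optional[str] = None  # "healthy" | "OA" for cartilage
    seed: Optional[int] = None
    strict: bool = True

    def __post_init__(self) -> None:
        h = np.asarray(self.hydration, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        object.__setattr__(self, "hydration", h)
        object.__setattr__(self, "pressure", p)
        if h.ndim != 1 or p.shape != h.shape:
            raise CurveValidationError(
                f"curve '{self.label}': hydration and pressure must be "
                f"1-D arrays of equal length"
            )
        if len(h) < 2:
            raise CurveValidationError(
                f"curve '{self.label}': need at least two points"
            )
        if not np.all(np.isfinite(h)) or not np.all(np.isfinite(p)):
            raise CurveValidationError(
                f"curve '{self.label}': non-finite values"
            )
        if np.any(np.diff(h) <= 0):
            i = int(np.nonzero(np.diff(h) <= 0)[0][0])
            raise CurveValidationError(
                f"curve '{self.label}': hydration not strictly increasing "
                f"at point {i + 1} (h={h[i + 1]:g} after h={h[i]:g})"
            )
        if self.strict:
            if np.any(h < 1.0):
                raise CurveValidationError(
                    f"curve '{self.label}': hydration must be >= 1"
                )
            if np.any(np.diff(p) >= 0):
                i = int(np.nonzero(np.diff(p) >= 0)[0][0])
                raise CurveValidationError(
                    f"curve '{self.label}': pressure not strictly "
                    f"decreasing at point {i + 1} "
                    f"(p={p[i + 1]:g} kPa after p={p[i]:g} kPa)"
                )

    # -- interpolation ------------------------------------------------

    def interpolant(self) -> PchipInterpolator:
        """Monotone piecewise-cubic interpolant of pressure(hydration)."""
        return PchipInterpolator(self.hydration, self.pressure, extrapolate=False)

    def pressure_at(self, h: float | np.ndarray) -> float | np.ndarray:
        """Interpolated pressure at hydration(s) h; NaN outside range."""
        out = self.interpolant()(h)
        return float(out) if np.isscalar(h) else out

    # -- derived quantities -------------------------------------------

    @property
    def phi(self) -> np.ndarray:
        """Polymer volume fraction 1/hydration at each point."""
        return 1.0 / self.hydration

    @property
    def hmin(self) -> float:
        return float(self.hydration[0])

    @property
    def hmax(self) -> float:
        return float(self.hydration[-1])

    def overlap(self, other: "SwellingCurve") -> tuple[float, float]:
        """Shared hydration range with another curve.

        Raises
        ------
        CurveValidationError
            If the two ranges are disjoint.
        """
        lo = max(self.hmin, other.hmin)
        hi = min(self.hmax, other.hmax)
        if lo >= hi:
            raise CurveValidationError(
                f"curves '{self.label}' and '{other.label}' have disjoint "
                f"hydration ranges [{self.hmin:g}, {self.hmax:g}] and "
                f"[{other.hmin:g}, {other.hmax:g}]"
            )
        return lo, hi

    def resampled(self, hydration: np.ndarray) -> "SwellingCurve":
        """Curve re-evaluated on a new hydration grid (interpolated)."""
        h = np.asarray(hydration, dtype=float)
        return replace(self, hydration=h, pressure=self.interpolant()(h),
                       strict=False)

    def scaled(self, factor: float) -> "SwellingCurve":
        """Curve with all pressures multiplied by a common factor."""
        return replace(self, pressure=self.pressure * factor)

    def as_strict(self) -> "SwellingCurve":
        """Re-validate this curve under the analysis (strict) contract."""
        return replace(self, strict=True)
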