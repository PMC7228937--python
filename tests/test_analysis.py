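"""Curve-level analysis: zeros, intersections, prestress, K_os, Fung."""

import numpy as np
import pytest

from cartigel.analysis import (
    NoPrestressError,
    NoZeroCrossingError,
    PrestressCurve,
    find_equilibrium,
    find_intersection,
    fit_fung,
    kos_ratio,
    osmotic_modulus,
    prestress_curve,
)
from cartigel.curves import CurveValidationError, SwellingCurve
from cartigel.params import BathConditions

BATH = BathConditions()


def linear_curve(a, b, h=None, label="lin"):
    """Pressure a - b*h sampled on integer hydrations (strictly decreasing)."""
    h = np.arange(1.0, 7.0) if h is None else np.asarray(h, float)
    return SwellingCurve(hydration=h, pressure=a - b * h, label=label, bath=BATH)


class TestFindEquilibrium:
    def test_linear_construction(self):
        # Pi(h) = 100 (4 - h) crosses zero at exactly h = 4
        c = linear_curve(400.0, 100.0)
        assert find_equilibrium(c) == pytest.approx(4.0, abs=1e-10)

    def test_round_trip_with_forward_model(self, ph7):
        from cartigel.composite import (
            composite_curves,
            composite_equilibrium_volume_fraction,
        )

        comp, bath = ph7
        h_eq_model = 1.0 / composite_equilibrium_volume_fraction(comp, bath)
        grid = np.linspace(3.0, 1.2 * h_eq_model, 300)
        c, _ = composite_curves(comp, bath, grid)
        assert find_equilibrium(c) == pytest.approx(h_eq_model, rel=1e-6)

    def test_all_positive_curve_refused(self):
        c = linear_curve(1000.0, 10.0)  # never reaches zero on h in [1,6]
        with pytest.raises(NoZeroCrossingError):
            find_equilibrium(c)


class TestFindIntersection:
    def test_linear_crossing(self):
        # 100 - 20h and 40 - 5h meet at h = 4 (both 20 kPa)
        a = linear_curve(100.0, 20.0, label="a")
        b = linear_curve(40.0, 5.0, label="b")
        assert find_intersection(a, b) == pytest.approx(4.0, abs=1e-10)

    def test_ph1_preset_has_none(self, ph1_curves):
        c, f = ph1_curves
        assert find_intersection(c, f) is None

    def test_agrees_with_dense_sign_scan_oracle(self, ph7_curves):
        c, f = ph7_curves
        h = np.linspace(c.hmin, c.hmax, 100_000)
        d = f.interpolant()(h) - c.interpolant()(h)
        sgn = np.sign(d)
        scan = h[:-1][sgn[:-1] * sgn[1:] < 0]
        step = h[1] - h[0]
        found = find_intersection(c, f)
        assert found is not None
        assert min(abs(scan - found)) <= step

    def test_disjoint_ranges_error(self):
        a = linear_curve(100.0, 20.0, h=[1.0, 2.0, 3.0])
        b = linear_curve(100.0, 20.0, h=[5.0, 6.0, 7.0])
        with pytest.raises(CurveValidationError):
            find_intersection(a, b)


class TestPrestressCurve:
    def test_pointwise_difference(self):
        filler = linear_curve(16.0, 1.0, label="f")  # 10 kPa at h=6...
        composite = linear_curve(10.0, 1.0, label="c")
        pre = prestress_curve(filler, composite)
        # Pi_f - Pi_c = 6 kPa everywhere
        assert np.allclose(pre.p_el, 6.0)

    def test_max_prestress_at_equilibrium(self, ph7_curves):
        c, f = ph7_curves
        pre = prestress_curve(f, c)
        assert pre.equilibrium_hydration is not None
        # at h_eq the composite pressure is 0, so P_el = Pi_filler there
        assert pre.p_el_max == pytest.approx(
            float(f.interpolant()(pre.equilibrium_hydration)), rel=1e-3
        )

    def test_steep_rise_between_intersection_and_equilibrium(self, ph7_curves):
        # P_el rises steeply over the prestress region; under the
        # volume-weighted coupling rule a stiffened composite (K_f > K_m
        # at equilibrium) necessarily bends P_el over just below h_eq,
        # so strict monotonicity is asserted over the rise and the
        # terminal sag is bounded at a few percent of the maximum.
        c, f = ph7_curves
        pre = prestress_curve(f, c)
        inside = pre.hydration <= pre.equilibrium_hydration
        peak_idx = int(np.argmax(np.where(inside, pre.p_el, -np.inf)))
        h_peak = pre.hydration[peak_idx]
        assert h_peak > 1.4 * pre.intersection_hydration
        m = (pre.hydration >= pre.intersection_hydration) & (
            pre.hydration <= h_peak
        )
        assert np.all(np.diff(pre.p_el[m]) > 0)
        # terminal sag from the interior peak to h_eq stays bounded
        assert pre.p_el_max > 0.5 * pre.p_el[peak_idx]
        assert pre.p_el_max > 10 * pre.p_el[m][0]

    def test_zero_at_intersection(self, ph7_curves):
        c, f = ph7_curves
        pre = prestress_curve(f, c)
        h0 = pre.intersection_hydration
        val = f.interpolant()(h0) - c.interpolant()(h0)
        assert abs(val) < 1e-3 * max(1.0, pre.p_el_max)

    def test_antisymmetry_under_swap(self, ph7_curves):
        c, f = ph7_curves
        pre = prestress_curve(f, c)
        swapped = prestress_curve(c, f)
        pos = pre.p_el > 1e-9
        assert np.all(swapped.p_el[pos] == 0.0)

    def test_resampling_invariance(self, ph7):
        from cartigel.composite import (
            composite_curves,
            composite_equilibrium_volume_fraction,
        )

        comp, bath = ph7
        h_eq = 1.0 / composite_equilibrium_volume_fraction(comp, bath)
        out = {}
        for n in (150, 300):
            grid = np.linspace(3.0, 1.15 * h_eq, n)
            c, f = composite_curves(comp, bath, grid)
            pre = prestress_curve(f, c)
            out[n] = (pre.intersection_hydration, pre.equilibrium_hydration,
                      pre.p_el_max)
        for a, b in zip(out[150], out[300]):
            assert a == pytest.approx(b, rel=1e-2)


class TestOsmoticModulus:
    def test_power_law_curve(self):
        # Pi = C phi^(9/4): K_os = (9/4) Pi, so 40 kPa -> 90 kPa
        h = np.linspace(2.0, 20.0, 400)
        phi_q = 0.1
        C = 40.0 / phi_q ** (9 / 4)
        curve = SwellingCurve(hydration=h, pressure=C * (1 / h) ** (9 / 4),
                              label="power")
        res = osmotic_modulus(curve, phi_q)
        assert res.k_os == pytest.approx(90.0, rel=1e-4)

    def test_constant_curve_zero_modulus(self):
        h = np.linspace(2.0, 10.0, 50)
        curve = SwellingCurve(hydration=h, pressure=np.full_like(h, 5.0),
                              label="flat", strict=False)
        assert osmotic_modulus(curve, 0.2).k_os == pytest.approx(0.0, abs=1e-9)

    def test_curve_path_matches_analytic_path(self, pva1):
        params, bath = pva1
        h = np.linspace(4.0, 18.0, 400)
        from cartigel.thermo import swelling_pressure_only

        pressure = np.asarray(swelling_pressure_only(1.0 / h, params, bath))
        curve = SwellingCurve(hydration=h, pressure=pressure, label="pva1")
        for phi in (0.08, 0.1, 0.15):
            fd = osmotic_modulus(curve, phi).k_os
            an = osmotic_modulus(params, phi, bath).k_os
            assert fd == pytest.approx(an, rel=5e-3)

    def test_boundary_phi_rejected(self):
        h = np.linspace(2.0, 10.0, 50)
        curve = SwellingCurve(hydration=h, pressure=100.0 - 5.0 * h, label="lin")
        with pytest.raises(ValueError):
            osmotic_modulus(curve, 0.5)  # hydration 2 = range boundary


class TestKosRatio:
    def test_identical_curves_unity(self, ph7_curves):
        c, _ = ph7_curves
        assert kos_ratio(c, c, 10.0) == pytest.approx(1.0, rel=1e-12)

    def test_homogeneity_under_pressure_scaling(self, ph7_curves):
        c, _ = ph7_curves
        assert kos_ratio(c, c.scaled(0.5), 10.0) == pytest.approx(2.0, rel=1e-9)
        # common rescaling of both curves leaves the ratio unchanged
        assert kos_ratio(c.scaled(3.0), c.scaled(1.5), 10.0) == pytest.approx(
            2.0, rel=1e-9
        )


def make_fung_prestress(a=5.0, b=2.0, h0=3.0, n=30):
    h = np.linspace(h0, h0 + 2.0, n)
    p = a * np.expm1(b * (h - h0))
    return PrestressCurve(
        hydration=h, p_el=p, intersection_hydration=h0,
        equilibrium_hydration=h[-1], p_el_max=p[-1],
    )


class TestFungFit:
    def test_exact_recovery_on_model_data(self):
        pre = make_fung_prestress()
        fit = fit_fung(pre)
        assert fit.rmse < 1e-6
        assert fit.amplitude == pytest.approx(5.0, rel=1e-4)
        assert fit.rate == pytest.approx(2.0, rel=1e-4)
        assert fit.onset_hydration == pytest.approx(3.0, abs=1e-4)

    def test_beats_grid_search_oracle(self, ph7_curves):
        c, f = ph7_curves
        pre = prestress_curve(f, c)
        fit = fit_fung(pre)
        h, p = pre.positive_points()
        # coarse 20^3 grid-search oracle over (A, b, h0)
        best = np.inf
        for a in np.geomspace(0.1, 1000.0, 20):
            for b in np.geomspace(0.01, 3.0, 20):
                for h0 in np.linspace(h[0] - 10.0, h[0] - 1e-6, 20):
                    r = a * np.expm1(b * (h - h0)) - p
                    best = min(best, float(np.sqrt(np.mean(r * r))))
        assert fit.rmse <= best + 1e-9

    def test_all_zero_prestress_refused(self):
        pre = PrestressCurve(
            hydration=np.linspace(2, 10, 20), p_el=np.zeros(20),
            intersection_hydration=None, equilibrium_hydration=None,
            p_el_max=None,
        )
        with pytest.raises(NoPrestressError):
            fit_fung(pre)

    def test_too_few_points_refused(self):
        pre = make_fung_prestress(n=3)
        with pytest.raises(ValueError):
            fit_fung(pre)
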