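"""Closed-form curve, root algebra and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from phenokin import (
    ComplexRootsError,
    DegenerateModelError,
    DerivedKinetics,
    KineticCoefficients,
    KineticsError,
    coefficients_from_roots,
    concentration_at,
    consumption_rate,
    derive_parameters,
)
from phenokin.simulate import draw_reference_like_kinetics


def integrate_rate_law(coeffs, s0, t_eval):
    """Independent oracle: adaptive numerical integration of the rate ODE."""
    sol = solve_ivp(
        lambda t, s: consumption_rate(s, coeffs),
        (0.0, float(max(t_eval))), [s0], t_eval=np.asarray(t_eval, float),
        method="RK45", rtol=1e-10, atol=1e-8,
    )
    assert sol.success
    return sol.y[0]


class TestConsumptionRate:
    def test_vanishes_at_both_roots(self, reactor_a_coeffs, reactor_a_kinetics):
        d = reactor_a_kinetics
        assert consumption_rate(d.q, reactor_a_coeffs) == pytest.approx(0.0, abs=1e-12)
        assert consumption_rate(d.h, reactor_a_coeffs) == pytest.approx(0.0, abs=1e-12)

    def test_reference_reactor_initial_rate(self, reactor_a_coeffs):
        # direct polynomial evaluation at the measured initial concentration
        rate = consumption_rate(1081.7, reactor_a_coeffs)
        assert rate == pytest.approx(-0.2054689862, rel=1e-9)
        assert rate < 0  # substrate is being consumed

    def test_vectorized_evaluation(self, reactor_a_coeffs):
        s = np.array([300.0, 600.0, 900.0])
        rates = consumption_rate(s, reactor_a_coeffs)
        assert rates.shape == (3,)
        assert np.all(rates < 0)


class TestDeriveParameters:
    def test_symmetric_quadratic_by_hand(self):
        # K0=1, K1=0, K2=-1: discriminant 4, roots +-1
        d = derive_parameters(KineticCoefficients(k0=1.0, k1=0.0, k2=-1.0))
        assert (d.p, d.q, d.h) == (2.0, -1.0, 1.0)

    def test_reference_reactor_full_precision(self, reactor_a_coeffs):
        d = derive_parameters(reactor_a_coeffs)
        assert d.p == pytest.approx(0.0040400693, rel=1e-8)
        assert d.q == pytest.approx(221.7116, rel=1e-6)
        assert d.h == pytest.approx(1135.7544, rel=1e-6)
        # the reported table rounds p to 0.004 and prints q, h from the
        # rounded coefficients; agreement is within ~2%
        assert round(d.p, 3) == 0.004
        assert d.q == pytest.approx(223.4, rel=0.02)
        assert d.h == pytest.approx(1129.36, rel=0.02)

    def test_complex_roots_rejected(self):
        with pytest.raises(ComplexRootsError):
            derive_parameters(KineticCoefficients(k0=-1.0, k1=0.001, k2=-1.0))

    def test_first_order_degenerate_rejected(self):
        with pytest.raises(DegenerateModelError):
            derive_parameters(KineticCoefficients(k0=-1.0, k1=0.01, k2=0.0))

    def test_roots_are_ordered_with_swap_warning(self):
        # k2 > 0 flips the assignment of Eq. 6/7; q must still come out lower
        with pytest.warns(UserWarning, match="swap"):
            d = derive_parameters(KineticCoefficients(k0=-1.0, k1=0.0, k2=1.0))
        assert d.q < d.h


class TestCoefficientsFromRoots:
    def test_inverse_of_symmetric_case(self):
        c = coefficients_from_roots(p=2.0, q=-1.0, h=1.0)
        assert (c.k0, c.k1, c.k2) == (1.0, 0.0, -1.0)

    def test_inverse_of_reference_reactor(self, reactor_a_kinetics):
        d = reactor_a_kinetics
        c = coefficients_from_roots(d.p, d.q, d.h)
        assert c.k2 == pytest.approx(-4.42e-6, rel=1e-9)
        assert c.k1 == pytest.approx(0.006, rel=1e-9)
        assert c.k0 == pytest.approx(-1.113, rel=1e-9)

    def test_coincident_roots_rejected(self):
        with pytest.raises(DegenerateModelError):
            coefficients_from_roots(p=0.01, q=100.0, h=100.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.floats(1e-4, 1.0),
        q=st.floats(0.0, 500.0),
        span=st.floats(1.0, 2000.0),
    )
    def test_round_trip_identity(self, p, q, span):
        h = q + span
        d = derive_parameters(coefficients_from_roots(p, q, h))
        assert d.p == pytest.approx(p, rel=1e-10)
        assert d.q == pytest.approx(q, rel=1e-10, abs=1e-10)
        assert d.h == pytest.approx(h, rel=1e-10)


class TestConcentrationCurve:
    def test_initial_condition_and_asymptote(self, reactor_a_kinetics):
        d = reactor_a_kinetics
        assert concentration_at(0.0, d) == pytest.approx(d.s0, rel=1e-14)
        assert concentration_at(1e6, d) == pytest.approx(d.q, rel=1e-6)

    def test_reference_reactor_endpoint(self, reactor_a_kinetics):
        # closed form at the end of the 504 h campaign
        assert concentration_at(504.0, reactor_a_kinetics) == pytest.approx(
            838.659, abs=0.01
        )

    def test_monotone_decay_never_below_residual(self, rng):
        for _ in range(10):
            d = draw_reference_like_kinetics(rng)
            t = np.linspace(0.0, 5.0 / d.p, 400)
            s = concentration_at(t, d)
            assert np.all(np.diff(s) < 0)
            assert np.all(s > d.q)
            assert np.all(s <= d.s0 * (1 + 1e-12))

    def test_matches_numeric_ode_integration(self, rng):
        # oracle equivalence over 20 random valid parameter sets
        t = np.linspace(0.0, 504.0, 15)
        for _ in range(20):
            d = draw_reference_like_kinetics(rng)
            closed = concentration_at(t, d)
            numeric = integrate_rate_law(
                coefficients_from_roots(d.p, d.q, d.h), d.s0, t
            )
            assert np.max(np.abs(closed - numeric) / numeric) < 1e-6

    def test_lag_phase_when_start_near_upper_root(self, rng):
        # slow start: first 100 h window drops less than any later 100 h
        # window up to the inflection point at (q+h)/2
        for _ in range(10):
            q = rng.uniform(25, 235)
            s0 = rng.uniform(1000, 1350)
            h = s0 * rng.uniform(1.001, 1.05)  # s0 within 5% of h
            d = DerivedKinetics(p=rng.uniform(0.005, 0.02), q=q, h=h, s0=s0)
            edges = np.arange(0.0, 2000.0, 100.0)
            s = concentration_at(edges, d)
            drops = -np.diff(s)
            midpoint = 0.5 * (d.q + d.h)
            later = [dr for dr, s_end in zip(drops[1:], s[2:]) if s_end > midpoint]
            assert all(drops[0] < dr for dr in later)

    def test_invalid_inputs_rejected(self, reactor_a_kinetics):
        with pytest.raises(KineticsError):
            concentration_at(-1.0, reactor_a_kinetics)
        with pytest.raises(KineticsError):
            concentration_at(10.0, DerivedKinetics(p=0.01, q=100.0, h=1000.0))
        with pytest.raises(KineticsError):  # s0 outside (q, h]
            concentration_at(10.0, DerivedKinetics(p=0.01, q=100.0, h=1000.0, s0=50.0))

    def test_flat_curve_when_start_equals_upper_root(self):
        d = DerivedKinetics(p=0.035, q=23.84, h=1325.9, s0=1325.9)
        s = concentration_at(np.array([0.0, 100.0, 360.0]), d)
        assert np.allclose(s, 1325.9)
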