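"""Closed-form quadratic substrate-consumption kinetics.

The substrate concentration ``S`` (mg/L) in a batch reactor is assumed to
decay at a rate given by a second-degree polynomial of the concentration
itself,

    dS/dt = -(K2*S**2 + K1*S + K0),

a Riccati equation.  For a biologically meaningful fit the polynomial has
two real roots ``q < h``: ``q`` is the non-biodegradable residual the curve
approaches as t -> infinity, and ``h`` (slightly above the starting
concentration in practice) is the maximum substrate concentration that can
be turned over.  Between the roots the polynomial ``K2*S**2 + K1*S + K0``
is positive (fitted ``K2`` and ``K0`` are negative, ``K1`` positive), so
``S`` decreases monotonically from its initial value ``S0`` toward ``q``.

The equation integrates in closed form to a logistic-type decay

    S(t) = [h*(S0 - q) - q*(S0 - h)*exp(p*t)] / [(S0 - q) - (S0 - h)*exp(p*t)]

with rate constant ``p = sqrt(K1**2 - 4*K2*K0)`` (h^-1), the square root of
the discriminant.  When ``S0`` is close to ``h`` the early decay is nearly
flat — the lag/acclimatization phase of the microbial community — before
the curve bends down toward ``q``.

The algebra between the polynomial coefficients ``(K0, K1, K2)`` and the
root-space parameters ``(p, q, h)`` is exact in both directions:
:func:`derive_parameters` and :func:`coefficients_from_roots` are inverse
maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "KineticsError",
    "ComplexRootsError",
    "DegenerateModelError",
    "KineticCoefficients",
    "DerivedKinetics",
    "consumption_rate",
    "derive_parameters",
    "coefficients_from_roots",
    "concentration_at",
]


class KineticsError(ValueError):
    """Invalid kinetic parameters or model evaluation."""


class ComplexRootsError(KineticsError):
    """Discriminant K1^2 - 4*K2*K0 < 0: the rate polynomial has complex
    roots and the logistic-type closed form does not exist."""


class DegenerateModelError(KineticsError):
    """K2 = 0 (first-order rate law) or coincident roots: q and h are
    undefined and the quadratic model does not apply."""


@dataclass(frozen=True)
class KineticCoefficients:
    """Coefficients of the quadratic rate law.

    Attributes
    ----------
    k0 : float
        Constant term, mg L^-1 h^-1.
    k1 : float
        First-order coefficient, h^-1.
    k2 : float
        Second-order coefficient, L mg^-1 h^-1.
    """

    k0: float
    k1: float
    k2: float

    @property
    def discriminant(self) -> float:
        """k1**2 - 4*k2*k0; must be >= 0 for real roots."""
        return self.k1 ** 2 - 4.0 * self.k2 * self.k0

    @property
    def is_biologically_valid(self) -> bool:
        """True when the signs match a decaying substrate curve.

        Accepted fits have k2 < 0 and k0 < 0 (with k1 > 0), which places
        the decay window between two positive roots.
        """
        return self.k2 < 0 and self.k0 < 0 and self.discriminant >= 0


@dataclass(frozen=True)
class DerivedKinetics:
    """Root-space parameters of the consumption curve.

    Attributes
    ----------
    p : float
        Maximum specific rate (h^-1); sqrt of the rate-polynomial
        discriminant.
    q : float
        Non-biodegradable substrate concentration (mg/L); lower root and
        t -> infinity asymptote.
    h : float
        Maximum invertible substrate concentration (mg/L); upper root.
    s0 : float, optional
        Initial substrate concentration (mg/L).  Required by
        :func:`concentration_at`; may be omitted for pure root algebra.
    """

    p: float
    q: float
    h: float
    s0: Optional[float] = None

    def with_s0(self, s0: float) -> "DerivedKinetics":
        return replace(self, s0=s0)

    def validate(self, *, require_s0: bool = False) -> None:
        if not math.isfinite(self.p) or self.p <= 0:
            raise KineticsError(f"rate constant p must be finite and > 0, got {self.p}")
        if self.h <= self.q:
            raise DegenerateModelError(f"roots must satisfy q < h, got q={self.q}, h={self.h}")
        if require_s0:
            if self.s0 is None:
                raise KineticsError("s0 is required for curve evaluation but is unset")
            if not (self.q < self.s0 <= self.h):
                raise KineticsError(
                    f"initial concentration must satisfy q < s0 <= h, "
                    f"got q={self.q}, s0={self.s0}, h={self.h}"
                )


def consumption_rate(s, coeffs: KineticCoefficients):
    """Instantaneous rate of concentration change dS/dt (mg L^-1 h^-1).

    Evaluates ``-(k2*s**2 + k1*s + k0)``; zero exactly at the roots q and h.
    Accepts scalar or array ``s``.
    """
    s = np.asarray(s, dtype=float)
    rate = -(coeffs.k2 * s ** 2 + coeffs.k1 * s + coeffs.k0)
    return rate if rate.ndim else float(rate)


def derive_parameters(coeffs: KineticCoefficients, s0: Optional[float] = None) -> DerivedKinetics:
    """Map polynomial coefficients to the root-space parameters (p, q, h).

    p = sqrt(k1^2 - 4 k2 k0), q = (-k1 + p)/(2 k2), h = (-k1 - p)/(2 k2).
    ``q`` is always reported as the smaller root and ``h`` as the larger;
    if the formulae assign them the other way round (possible for unusual
    coefficient signs) they are swapped with a warning.

    Raises
    ------
    ComplexRootsError
        If the discriminant is negative.
    DegenerateModelError
        If k2 == 0 (the quadratic model degenerates to first order).
    """
    if coeffs.k2 == 0:
        raise DegenerateModelError("k2 = 0: degenerate first-order model, q and h undefined")
    disc = coeffs.discriminant
    if disc < 0:
        raise ComplexRootsError(f"negative discriminant {disc}: complex roots")
    p = math.sqrt(disc)
    q = (-coeffs.k1 + p) / (2.0 * coeffs.k2)
    h = (-coeffs.k1 - p) / (2.0 * coeffs.k2)
    if q > h:
        warnings.warn(
            "root formulae assigned q > h; swapping so that q is the lower root",
            stacklevel=2,
        )
        q, h = h, q
    return DerivedKinetics(p=p, q=q, h=h, s0=s0)


def coefficients_from_roots(p: float, q: float, h: float) -> KineticCoefficients:
    """Exact inverse of :func:`derive_parameters`.

    Given rate constant ``p`` and roots ``q < h``, reconstructs
    k2 = -p/(h - q), k1 = -k2*(q + h), k0 = k2*q*h, so that the round trip
    through :func:`derive_parameters` is the identity to machine precision.
    """
    if h == q:
        raise DegenerateModelError("coincident roots q == h")
    if p <= 0:
        raise KineticsError(f"rate constant p must be > 0, got {p}")
    k2 = -p / (h - q)
    k1 = -k2 * (q + h)
    k0 = k2 * q * h
    return KineticCoefficients(k0=k0, k1=k1, k2=k2)


def concentration_at(t, params: DerivedKinetics):
    """Closed-form substrate concentration S(t) in mg/L.

    Evaluates the logistic-type solution of the quadratic rate law.  For
    numerical stability at large ``p*t`` the expression is computed with
    ``exp(-p*t)``:

        S(t) = [h*(s0 - q)*E - q*(s0 - h)] / [(s0 - q)*E - (s0 - h)],
        E = exp(-p*t)

    which is algebraically identical to the ``exp(+p*t)`` form and tends to
    ``q`` as t -> infinity without overflow.  S(0) = s0 exactly, and S is
    monotonically non-increasing for q < s0 <= h (constant when s0 == h).

    Parameters
    ----------
    t : scalar or array
        Time in hours, >= 0.
    params : DerivedKinetics
        Must carry a valid ``s0`` with q < s0 <= h.
    """
    params.validate(require_s0=True)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise KineticsError("time must be >= 0")
    s = _curve_unchecked(t, params.p, params.q, params.h, params.s0)
    return s if s.ndim else float(s)


def _curve_unchecked(t, p, q, h, s0):
    """Curve evaluation without precondition checks (used inside fitting,
    where intermediate parameter proposals may be transiently invalid)."""
    t = np.asarray(t, dtype=float)
    e = np.exp(-p * t)
    num = h * (s0 - q) * e - q * (s0 - h)
    den = (s0 - q) * e - (s0 - h)
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den
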