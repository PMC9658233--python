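"""Nonlinear least-squares estimation of consumption-curve parameters.

A reactor time series (hours, mg/L) is fitted by minimising the sum of
squared deviations between observed concentrations and the closed-form
curve.  The optimisation runs in root space (p, q, h), optionally also over
S0, because the bounds

    p > 0,    0 <= q < min(S),    h >= max(S)

directly encode model validity and keep the search away from
complex-root territory; the polynomial coefficients (K0, K1, K2) are then
recovered through the exact inverse map.  Goodness of fit is summarised by
R, the Pearson correlation between observed and fitted concentrations,
with R**2 reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import (
    DerivedKinetics,
    KineticCoefficients,
    KineticsError,
    _curve_unchecked,
    coefficients_from_roots,
)

__all__ = [
    "FitError",
    "ReactorSeries",
    "FitResult",
    "goodness_R",
    "auto_initialize",
    "fit_series",
]

#: Pearson R below which a fit is flagged as poorly determined.  Accepted
#: reactor fits in practice sit at R >= 0.9 while an uninformative
#: (flat, control-like) series gives R around 0.4 or below.
DEFAULT_R_THRESHOLD = 0.7

_FTOL = 1e-10
_XTOL = 1e-10
_MAX_NFEV = 10_000
_MAX_RESTARTS = 5


class FitError(RuntimeError):
    """Fit could not be completed; the message carries diagnostics."""


@dataclass(frozen=True)
class ReactorSeries:
    """One reactor x analyte concentration time series.

    times are hours, strictly increasing and >= 0; concentrations are
    mg/L, >= 0, one per time point.
    """

    reactor_id: str
    analyte: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", s)
        if t.ndim != 1 or s.ndim != 1 or len(t) != len(s):
            raise ValueError("times and concentrations must be 1-D and of equal length")
        if len(t) and t[0] < 0:
            raise ValueError("times must be >= 0")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class FitResult:
    """Estimated parameters and fit diagnostics for one series."""

    derived: DerivedKinetics
    coeffs: KineticCoefficients
    r: float
    r_squared: float
    residuals: np.ndarray
    standard_errors: dict = field(default_factory=dict)
    n_obs: int = 0
    n_params: int = 3
    sse: float = float("nan")
    converged: bool = False
    good_fit: bool = False
    message: str = ""

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_params

    def predicted(self, t) -> np.ndarray:
        d = self.derived
        return _curve_unchecked(np.asarray(t, dtype=float), d.p, d.q, d.h, d.s0)


def goodness_R(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson correlation R between observed and model concentrations.

    Raises
    ------
    ValueError
        If lengths differ, fewer than 2 points, or either vector has zero
        variance (R undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    if len(obs) < 2:
        raise ValueError("at least 2 points are required")
    if np.ptp(obs) == 0 or np.std(obs) == 0:
        raise ValueError("R undefined: observed values have zero variance")
    if np.ptp(pred) == 0 or np.std(pred) == 0:
        raise ValueError("R undefined: predicted values have zero variance")
    return float(np.corrcoef(obs, pred)[0, 1])


def auto_initialize(series: ReactorSeries) -> DerivedKinetics:
    """Starting values for the optimiser from simple curve geometry.

    q0 = 0.5*min(S); h0 = 1.02*max(S); s0 = first observation; p0 from an
    ordinary least-squares slope of the logit transform
    ln[(S - q0)/(h0 - S)] against -t over points strictly inside (q0, h0),
    floored at 1e-4 h^-1.  Falls back to p0 = 0.005 h^-1 when fewer than
    two interior points are usable.
    """
    s = series.concentrations
    t = series.times
    if len(series) < 2:
        raise ValueError("series too short to initialize")
    q0 = 0.5 * float(np.min(s))
    h0 = 1.02 * float(np.max(s))
    s0 = float(s[0])
    inside = (s > q0) & (s < h0)
    p0 = 0.005
    if inside.sum() >= 2:
        y = np.log((s[inside] - q0) / (h0 - s[inside]))
        x = -t[inside]
        slope = np.polyfit(x, y, 1)[0]
        p0 = max(float(slope), 1e-4)
    return DerivedKinetics(p=p0, q=q0, h=h0, s0=s0)


def _pack(init: DerivedKinetics, fix_s0: bool) -> np.ndarray:
    x = [init.p, init.q, init.h]
    if not fix_s0:
        x.append(init.s0)
    return np.asarray(x, dtype=float)


def _unpack(x: np.ndarray, s0_fixed: Optional[float]) -> DerivedKinetics:
    if s0_fixed is None:
        return DerivedKinetics(p=x[0], q=x[1], h=x[2], s0=x[3])
    return DerivedKinetics(p=x[0], q=x[1], h=x[2], s0=s0_fixed)


def fit_series(
    series: ReactorSeries,
    init: Optional[DerivedKinetics] = None,
    fix_s0: bool = True,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    max_restarts: int = _MAX_RESTARTS,
    restart_seed: int = 20221031,
) -> FitResult:
    """Fit the consumption curve to one reactor series.

    Minimises sum_i (S_i - S(t_i; p, q, h[, s0]))^2 with a bounded
    trust-region-reflective least-squares solver (the bound-constrained
    member of the Levenberg-Marquardt family).  On failure the
    initialisation is jittered deterministically up to ``max_restarts``
    times before a :class:`FitError` is raised.

    Parameters
    ----------
    series : ReactorSeries
        At least 4 points (3 free parameters + 1).
    init : DerivedKinetics, optional
        Starting point; :func:`auto_initialize` is used when omitted.
    fix_s0 : bool
        Fix the initial concentration to the first observation (default)
        or treat it as a fourth free parameter.
    r_threshold : float
        Fits with R below this are reported with ``good_fit=False``.
    """
    t = series.times
    s = series.concentrations
    if len(series) < 4:
        raise ValueError(f"need at least 4 points to fit, got {len(series)}")
    if np.ptp(s) == 0:
        raise FitError("constant series: no decay information to fit")

    if init is None:
        init = auto_initialize(series)
    s0_fixed = float(s[0]) if fix_s0 else None
    if init.s0 is None:
        init = init.with_s0(float(s[0]))

    smin, smax = float(np.min(s)), float(np.max(s))
    lo = [1e-8, 0.0, smax]
    hi = [10.0, smin * (1 - 1e-9), np.inf]
    if not fix_s0:
        lo.append(smin)
        hi.append(2.0 * smax)
    lo, hi = np.asarray(lo), np.asarray(hi)

    def residuals(x):
        d = _unpack(x, s0_fixed)
        return _curve_unchecked(t, d.p, d.q, d.h, d.s0) - s

    x0_base = np.clip(_pack(init, fix_s0), lo + 1e-12, np.where(np.isfinite(hi), hi, 1e12))
    rng = np.random.default_rng(restart_seed)
    scale = [0.01, max(smin, 1.0), max(smax, 1.0)] + ([] if fix_s0 else [max(smax, 1.0)])
    best = None
    messages = []
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            x0 = x0_base
        else:
            jitter = rng.normal(0.0, 0.25, size=x0_base.shape)
            x0 = np.clip(x0_base * np.exp(jitter), lo + 1e-12,
                         np.where(np.isfinite(hi), hi, 1e12))
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                ftol=_FTOL, xtol=_XTOL, gtol=1e-12, max_nfev=_MAX_NFEV,
                x_scale=scale,
            )
        except Exception as exc:  # pragma: no cover - solver-internal failure
            messages.append(f"attempt {attempt}: {exc}")
            continue
        if not res.success or not np.all(np.isfinite(res.x)):
            messages.append(f"attempt {attempt}: {res.message}")
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        raise FitError(
            "fit did not converge after "
            f"{max_restarts + 1} attempts on reactor {series.reactor_id!r} "
            f"({series.analyte}): " + "; ".join(messages)
        )

    derived = _unpack(best.x, s0_fixed)
    coeffs = coefficients_from_roots(derived.p, derived.q, derived.h)
    resid = residuals(best.x)
    sse = float(np.sum(resid ** 2))
    n = len(series)
    k = 3 if fix_s0 else 4

    errors = _standard_errors(best, sse, n, k, derived, fix_s0)
    predicted = _curve_unchecked(t, derived.p, derived.q, derived.h, derived.s0)
    try:
        r = goodness_R(s, predicted)
    except ValueError:
        r = float("nan")

    good = bool(np.isfinite(r) and r >= r_threshold)
    return FitResult(
        derived=derived,
        coeffs=coeffs,
        r=r,
        r_squared=r * r if np.isfinite(r) else float("nan"),
        residuals=resid,
        standard_errors=errors,
        n_obs=n,
        n_params=k,
        sse=sse,
        converged=True,
        good_fit=good,
        message="converged",
    )


def _standard_errors(res, sse, n, k, derived, fix_s0):
    """Asymptotic standard errors from the Jacobian at the optimum.

    cov = s^2 (J^T J)^+ with s^2 = SSE/(n-k); errors for the polynomial
    coefficients follow by the delta method through the exact
    root->coefficient map.
    """
    names = ["p", "q", "h"] + ([] if fix_s0 else ["s0"])
    errors = {name: float("nan") for name in names}
    if n <= k:
        return errors
    s2 = sse / (n - k)
    J = res.jac
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError:  # pragma: no cover
        return errors
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    errors.update(dict(zip(names, map(float, se))))

    p, q, h = derived.p, derived.q, derived.h
    d = h - q
    # gradients of (k2, k1, k0) wrt (p, q, h)
    g_k2 = np.array([-1.0 / d, -p / d ** 2, p / d ** 2])
    g_k1 = np.array([(q + h) / d, 2.0 * p * h / d ** 2, -2.0 * p * q / d ** 2])
    g_k0 = np.array([-q * h / d, -p * h ** 2 / d ** 2, p * q ** 2 / d ** 2])
    cov3 = cov[:3, :3]
    for name, g in (("k2", g_k2), ("k1", g_k1), ("k0", g_k0)):
        errors[name] = float(math.sqrt(max(float(g @ cov3 @ g), 0.0)))
    return errors
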