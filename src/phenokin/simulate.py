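"""Synthetic reactor time series with the structure the analysis assumes.

The original campaigns published only summary tables, not the raw series,
so testing the estimator requires regenerating data with the same
structure: the closed-form consumption curve sampled on the campaign's
sparse time grid, plus measurement noise.  Noise is additive Gaussian,
truncated at zero, with standard deviation defaulting to 2% of the
initial concentration — the order of the replicate scatter reported for
the phenol assays (e.g. 922 ± 6.1 mg/L).  Every stochastic call takes an
explicit seed; there is no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import FIRST_ASSAY_GRID_H, SECOND_ASSAY_GRID_H, reference_reactors
from .fitting import ReactorSeries
from .model import DerivedKinetics, concentration_at

__all__ = [
    "AssayDesign",
    "Assay",
    "generate_series",
    "generate_assay",
    "default_design",
    "draw_reference_like_kinetics",
    "parameter_recovery_study",
]

DEFAULT_NOISE_SD_FRAC = 0.02


@dataclass(frozen=True)
class AssayDesign:
    """Design of one simulated campaign.

    ``reactors`` holds (label, true kinetics) pairs; ``noise_sd_frac``
    scales each reactor's noise standard deviation as a fraction of its
    own s0.
    """

    name: str
    time_grid: tuple
    reactors: tuple
    noise_sd_frac: float = DEFAULT_NOISE_SD_FRAC
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "time_grid", tuple(float(t) for t in self.time_grid))
        object.__setattr__(self, "reactors", tuple(self.reactors))
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        labels = [lab for lab, _ in self.reactors]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate reactor labels in design: {labels}")


@dataclass(frozen=True)
class Assay:
    """Generated series bundled with the ground-truth parameters."""

    design: AssayDesign
    series: tuple
    truth: dict = field(default_factory=dict)


def generate_series(
    params: DerivedKinetics,
    grid: Sequence[float],
    noise_sd: float,
    seed: int,
    reactor_id: str = "sim",
    analyte: str = "phenol",
    replicates: int = 1,
) -> ReactorSeries:
    """One noisy realisation of the consumption curve on a time grid.

    S_i = max(0, S(t_i) + eps_i) with independent Gaussian eps of standard
    deviation ``noise_sd`` (mg/L).  With ``replicates`` > 1 the reported
    value at each time point is the mean of that many noisy replicates.
    Identical seeds give identical series.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    t = np.asarray(grid, dtype=float)
    clean = np.atleast_1d(np.asarray(concentration_at(t, params), dtype=float))
    rng = np.random.default_rng(seed)
    noisy = clean[None, :] + rng.normal(0.0, noise_sd, size=(replicates, len(t))) \
        if noise_sd > 0 else np.broadcast_to(clean, (replicates, len(t)))
    s = np.maximum(0.0, noisy).mean(axis=0)
    return ReactorSeries(reactor_id=reactor_id, analyte=analyte,
                         times=t, concentrations=s)


def generate_assay(design: AssayDesign) -> Assay:
    """Generate one series per reactor of a design, reproducibly.

    Per-reactor seeds are spawned from ``design.seed`` so that the whole
    assay is a deterministic function of the design.
    """
    seeds = np.random.SeedSequence(design.seed).generate_state(len(design.reactors))
    series = []
    truth = {}
    for (label, params), seed in zip(design.reactors, seeds):
        noise_sd = design.noise_sd_frac * float(params.s0)
        series.append(
            generate_series(params, design.time_grid, noise_sd, int(seed) % (2 ** 31),
                            reactor_id=label)
        )
        truth[label] = params
    return Assay(design=design, series=tuple(series), truth=truth)


def default_design(
    name: str,
    seed: int = 0,
    noise_sd_frac: float = DEFAULT_NOISE_SD_FRAC,
    reactors: Optional[Sequence] = None,
) -> AssayDesign:
    """Campaign design with the reference grid and reactor parameters.

    ``name`` selects the sampling grid: 'first' (7 points over 504 h) or
    'second' (8 points over 360 h).  Reactor parameterisations default to
    the published fits of the matching campaign.
    """
    grids = {"first": FIRST_ASSAY_GRID_H, "second": SECOND_ASSAY_GRID_H}
    if name not in grids:
        raise ValueError(f"unknown design {name!r}; expected 'first' or 'second'")
    if reactors is None:
        reactors = reference_reactors(name)
    return AssayDesign(name=name, time_grid=grids[name], reactors=tuple(reactors),
                       noise_sd_frac=noise_sd_frac, seed=seed)


def draw_reference_like_kinetics(rng: np.random.Generator) -> DerivedKinetics:
    """One random parameter set spanning the published reactor fits.

    p ~ U(0.002, 0.035) h^-1, q ~ U(25, 235) mg/L, s0 ~ U(1000, 1350) mg/L
    and h = s0 * U(1.01, 1.15) — uniform over the union of the parameter
    ranges of the eight published reactor fits.
    """
    p = rng.uniform(0.002, 0.035)
    q = rng.uniform(25.0, 235.0)
    s0 = rng.uniform(1000.0, 1350.0)
    h = s0 * rng.uniform(1.01, 1.15)
    return DerivedKinetics(p=p, q=q, h=h, s0=s0)


def parameter_recovery_study(
    n_replicates: int = 50,
    grid: Sequence[float] = SECOND_ASSAY_GRID_H,
    noise_sd_frac: float = DEFAULT_NOISE_SD_FRAC,
    seed: int = 12345,
) -> dict:
    """Simulate-and-refit experiment measuring parameter recovery.

    Each replicate draws a parameter set with
    :func:`draw_reference_like_kinetics`, generates one noisy series on
    ``grid`` (noise SD = ``noise_sd_frac`` * s0) and refits it.  Returns
    per-parameter relative-error arrays and their medians, plus the count
    of non-converged replicates.  Deterministic given ``seed``.
    """
    from .fitting import fit_series  # deferred: avoids import cycle

    rng = np.random.default_rng(seed)
    errors = {"p": [], "q": [], "h": []}
    failures = 0
    for _ in range(n_replicates):
        truth = draw_reference_like_kinetics(rng)
        series = generate_series(
            truth, grid, noise_sd_frac * truth.s0, int(rng.integers(2 ** 31))
        )
        try:
            fit = fit_series(series)
        except Exception:
            failures += 1
            continue
        errors["p"].append(abs(fit.derived.p - truth.p) / truth.p)
        errors["q"].append(abs(fit.derived.q - truth.q) / truth.q)
        errors["h"].append(abs(fit.derived.h - truth.h) / truth.h)
    medians = {k: float(np.median(v)) if v else float("nan") for k, v in errors.items()}
    return {"errors": {k: np.asarray(v) for k, v in errors.items()},
            "medians": medians, "failures": failures,
            "n_replicates": n_replicates}
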