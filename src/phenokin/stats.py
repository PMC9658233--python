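"""Removal summaries and comparison of fitted kinetic constants.

Removal of an analyte over a batch run is the signed percentage

    % removal = 100 - final * 100 / initial,

negative when the analyte increased (COD can rise in an uninoculated
control).  Fitted kinetic constants from two treatments are compared with
a Welch two-sample t-test built from each fit's asymptotic estimate and
standard error, with Welch-Satterthwaite degrees of freedom; each fit
contributes n_obs - n_params degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
from scipy import stats as sps

__all__ = [
    "RemovalSummary",
    "ConstantComparison",
    "removal_percent",
    "summarize_removal",
    "convert_rate",
    "compare_constant",
    "pairwise_comparisons",
]


@dataclass(frozen=True)
class RemovalSummary:
    """Initial/final concentration (mg/L) and signed percent removal."""

    analyte: str
    initial: float
    final: float
    percent: float


@dataclass(frozen=True)
class ConstantComparison:
    """Welch t-test between two fitted constants."""

    treatment_a: str
    treatment_b: str
    statistic: float
    dof: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def removal_percent(initial: float, final: float) -> float:
    """Signed percent removal, 100 - final*100/initial.

    ``initial`` must be > 0 and ``final`` >= 0; the result is negative when
    the analyte increased over the run.
    """
    if not initial > 0:
        raise ValueError(f"initial concentration must be > 0, got {initial}")
    if final < 0:
        raise ValueError(f"final concentration must be >= 0, got {final}")
    return 100.0 - final * 100.0 / initial


def summarize_removal(series) -> RemovalSummary:
    """Removal summary of a :class:`~phenokin.fitting.ReactorSeries`,
    taking the first and last observations as initial and final."""
    s = series.concentrations
    return RemovalSummary(
        analyte=series.analyte,
        initial=float(s[0]),
        final=float(s[-1]),
        percent=removal_percent(float(s[0]), float(s[-1])),
    )


def convert_rate(p_per_hour: float) -> float:
    """Convert a rate constant from h^-1 to d^-1 (multiply by 24)."""
    return p_per_hour * 24.0


def compare_constant(
    est_a: float,
    se_a: float,
    n_a: int,
    est_b: float,
    se_b: float,
    n_b: int,
    *,
    n_params: int = 3,
    alpha: float = 0.05,
    label_a: str = "a",
    label_b: str = "b",
) -> ConstantComparison:
    """Welch t-test on two independently fitted constants.

    t = (est_a - est_b)/sqrt(se_a^2 + se_b^2); degrees of freedom by
    Welch-Satterthwaite with per-fit dof n_i - n_params; two-sided p-value
    from Student's t distribution.  Equal estimates give t = 0, p = 1.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be > 0")
    if n_a < 4 or n_b < 4:
        raise ValueError("each fit needs at least 4 observations")
    va, vb = se_a ** 2, se_b ** 2
    dfa, dfb = n_a - n_params, n_b - n_params
    if dfa <= 0 or dfb <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    t = (est_a - est_b) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va ** 2 / dfa + vb ** 2 / dfb)
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return ConstantComparison(
        treatment_a=label_a,
        treatment_b=label_b,
        statistic=float(t),
        dof=float(dof),
        p_value=p,
        significant=bool(p <= alpha),
        alpha=alpha,
    )


def pairwise_comparisons(
    fits: Iterable[tuple[str, float, float, int]],
    *,
    n_params: int = 3,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[ConstantComparison]:
    """All pairwise Welch comparisons among labelled constants.

    ``fits`` yields (label, estimate, standard error, n_obs) tuples.  With
    ``bonferroni=True`` the significance threshold alpha is divided by the
    number of pairs (the p-values themselves are not altered).
    """
    items = list(fits)
    labels = [f[0] for f in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate treatment labels")
    pairs = list(combinations(items, 2))
    thr = alpha / len(pairs) if (bonferroni and pairs) else alpha
    out = []
    for (la, ea, sa, na), (lb, eb, sb, nb) in pairs:
        c = compare_constant(
            ea, sa, na, eb, sb, nb,
            n_params=n_params, alpha=thr, label_a=la, label_b=lb,
        )
        out.append(c)
    return out
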