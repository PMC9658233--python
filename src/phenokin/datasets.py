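"""Reference conditions of the two phenol bioremediation assay campaigns.

Two sequential-batch-reactor (SBR) campaigns on phenol-rich resin-industry
wastewater anchor this package: four 15 L reactors per campaign (treatments
A-D; D is the uninoculated control), phenol starting near 1000-1350 mg/L.
The first campaign sampled at 0, 24, 120, 216, 312, 408 and 504 h, the
second at 0, 72, 120, 168, 216, 264, 312 and 360 h.

This module stores the published summary numbers of those campaigns —
initial/final phenol and COD concentrations with their reported removal
percentages, and the fitted quadratic-rate-law parameter sets
(p, h, q, S0-q, K0, K1, K2, R) per reactor.  They serve as generator
defaults, worked-example inputs and regression anchors; the raw time
series themselves were never published, which is why the synthetic
generator exists.
"""

from __future__ import annotations

from .model import DerivedKinetics

__all__ = [
    "FIRST_ASSAY_GRID_H",
    "SECOND_ASSAY_GRID_H",
    "REMOVALS",
    "FITTED_PARAMS",
    "INITIAL_PHENOL",
    "reference_kinetics",
    "reference_reactors",
]

#: Sampling grids, hours.
FIRST_ASSAY_GRID_H = (0.0, 24.0, 120.0, 216.0, 312.0, 408.0, 504.0)
SECOND_ASSAY_GRID_H = (0.0, 72.0, 120.0, 168.0, 216.0, 264.0, 312.0, 360.0)

#: (assay, reactor, analyte) -> (initial mg/L, final mg/L, reported %).
#: Negative percent = net increase (COD rose in the first-campaign control).
REMOVALS = {
    ("first", "A", "phenol"): (1081.7, 858.3, 20.6),
    ("first", "B", "phenol"): (1081.7, 845.5, 21.8),
    ("first", "C", "phenol"): (1009.3, 950.7, 5.8),
    ("first", "D", "phenol"): (1081.7, 899.3, 16.8),
    ("first", "A", "cod"): (24750.0, 12611.1, 49.0),
    ("first", "B", "cod"): (24750.0, 19322.2, 21.9),
    ("first", "C", "cod"): (26167.0, 6988.8, 73.3),
    ("first", "D", "cod"): (24750.0, 29455.5, -19.0),
    ("second", "A", "phenol"): (1349.5, 1333.0, 1.2),
    ("second", "B", "phenol"): (1340.0, 1301.0, 2.9),
    ("second", "C", "phenol"): (1341.6, 1312.3, 2.2),
    ("second", "D", "phenol"): (1325.8, 1323.5, 0.2),
    ("second", "A", "cod"): (38567.0, 19211.1, 50.2),
    ("second", "B", "cod"): (47633.3, 25266.6, 47.0),
    ("second", "C", "cod"): (39466.6, 22966.6, 41.8),
    ("second", "D", "cod"): (40816.6, 36033.3, 11.7),
}

#: (assay, reactor) -> dict of fitted-phenol-curve parameters as reported:
#: p (h^-1), h (mg/L), q (mg/L), s0_minus_q (mg/L), k0, k1, k2, r.
FITTED_PARAMS = {
    ("first", "A"): dict(p=0.004, h=1129.36, q=223.4, s0_minus_q=858.0,
                         k0=-1.113, k1=0.006, k2=-4.42e-6, r=0.94),
    ("first", "B"): dict(p=0.006, h=1098.09, q=236.2, s0_minus_q=846.0,
                         k0=-1.805, k1=0.009, k2=-6.96e-6, r=0.90),
    ("first", "C"): dict(p=0.002, h=1151.00, q=58.6, s0_minus_q=951.0,
                         k0=-0.123, k1=0.002, k2=-1.83e-6, r=0.97),
    ("first", "D"): dict(p=0.002, h=1249.51, q=182.4, s0_minus_q=899.0,
                         k0=-0.427, k1=0.003, k2=-1.87e-6, r=0.97),
    ("second", "A"): dict(p=0.011, h=1352.76, q=88.29, s0_minus_q=1261.0,
                          k0=-1.0512, k1=0.013, k2=-8.80e-6, r=0.90),
    ("second", "B"): dict(p=0.002, h=1428.80, q=47.98, s0_minus_q=1292.0,
                          k0=-0.0805, k1=0.002, k2=-1.18e-6, r=0.95),
    ("second", "C"): dict(p=0.005, h=1361.34, q=63.68, s0_minus_q=1278.0,
                          k0=-0.3230, k1=0.005, k2=-3.73e-6, r=0.99),
    ("second", "D"): dict(p=0.035, h=1325.90, q=23.84, s0_minus_q=1302.0,
                          k0=-0.8400, k1=0.036, k2=-2.66e-5, r=0.40),
}

#: (assay, reactor) -> measured initial phenol concentration, mg/L.
INITIAL_PHENOL = {
    (assay, reactor): REMOVALS[(assay, reactor, "phenol")][0]
    for assay in ("first", "second")
    for reactor in "ABCD"
}


def reference_kinetics(assay: str, reactor: str) -> DerivedKinetics:
    """Reported (p, q, h) for one reactor, with s0 set to the measured
    initial phenol concentration of that reactor."""
    row = FITTED_PARAMS[(assay, reactor)]
    return DerivedKinetics(p=row["p"], q=row["q"], h=row["h"],
                           s0=INITIAL_PHENOL[(assay, reactor)])


def reference_reactors(assay: str) -> list[tuple[str, DerivedKinetics]]:
    """(label, kinetics) pairs for the four reactors of one campaign."""
    if assay not in ("first", "second"):
        raise ValueError(f"unknown assay {assay!r}; expected 'first' or 'second'")
    return [(r, reference_kinetics(assay, r)) for r in "ABCD"]
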