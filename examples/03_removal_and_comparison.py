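"""Removal percentages and a Welch test between fitted constants.

Recomputes signed percent removal (100 - final*100/initial) from the
published initial/final concentrations of the first campaign, then fits
two simulated reactors and asks whether their first-order constants K1
differ significantly.
"""

from phenokin import (
    compare_constant,
    convert_rate,
    default_design,
    fit_series,
    generate_assay,
    removal_percent,
)
from phenokin.datasets import REMOVALS

print("first campaign, signed % removal (negative = net increase):")
for reactor in "ABCD":
    ph = removal_percent(*REMOVALS[("first", reactor, "phenol")][:2])
    cod = removal_percent(*REMOVALS[("first", reactor, "cod")][:2])
    print(f"  reactor {reactor}:  phenol {ph:6.1f} %   COD {cod:6.1f} %")
print()

assay = generate_assay(default_design("second", seed=7))
fits = {s.reactor_id: fit_series(s) for s in assay.series[:2]}
fa, fb = fits["A"], fits["B"]
c = compare_constant(
    fa.coeffs.k1, fa.standard_errors["k1"], fa.n_obs,
    fb.coeffs.k1, fb.standard_errors["k1"], fb.n_obs,
    label_a="A", label_b="B",
)
print(f"K1(A) = {fa.coeffs.k1:.4f} h^-1, K1(B) = {fb.coeffs.k1:.4f} h^-1")
print(f"Welch t = {c.statistic:.2f} on {c.dof:.1f} dof, p = {c.p_value:.3f} "
      f"-> {'different' if c.significant else 'no significant difference'} "
      "at alpha = 0.05")
print(f"(a rate of 0.011 h^-1 is {convert_rate(0.011):.3f} d^-1)")
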