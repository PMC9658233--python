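"""Simulate a four-reactor campaign and refit every series.

Generates the first-campaign design (7 samples over 504 h, four reactors
with the published parameter sets, 2% measurement noise), refits each
series, and compares the recovered rate constant with the truth.
"""

from phenokin import default_design, fit_series, generate_assay

assay = generate_assay(default_design("first", seed=42))

print("reactor   true p    fitted p       q (mg/L)     h (mg/L)      R")
for series in assay.series:
    truth = assay.truth[series.reactor_id]
    fit = fit_series(series)
    d = fit.derived
    print(f"   {series.reactor_id}      {truth.p:.4f}    {d.p:.4f}    "
          f"{d.q:11.1f}  {d.h:11.1f}   {fit.r:.3f}")
print()
print("R is the Pearson correlation between observed and fitted curves; "
      "at this noise level the fast reactors are recovered well while the "
      "slow ones (p ~ 0.002 h^-1) are only weakly identified by 7 samples.")
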