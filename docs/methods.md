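# Methods

## Model and assumptions

The consumption rate of the tracked substrate (phenol, mg/L) in a closed,
well-mixed batch reactor is modelled as a quadratic polynomial of the
concentration, dS/dt = −(K₂S² + K₁S + K₀). The model is unstructured: it
carries no explicit biomass state, temperature dependence or inhibition
term; the quadratic term absorbs the adaptation (lag) behaviour of the
community. Between the polynomial's two real roots q < h the rate is
negative, so S decays monotonically from S₀ toward q, the
non-biodegradable residual. The equation is a Riccati ODE and integrates
in closed form to a logistic-type curve with rate constant
p = √(K₁² − 4K₂K₀).

Two conventions are fixed deliberately:

- **Sign convention.** The rate law is stated with an explicit leading
  minus. Fitted coefficient sets for decaying substrate have K₂ < 0,
  K₀ < 0, K₁ > 0, which makes K₂S² + K₁S + K₀ positive between the roots;
  only the negated form yields decay with S(∞) = q. The implementation
  treats this as the defining equation and the closed form is its exact
  solution (verified against adaptive ODE integration to < 10⁻⁶ relative
  error in the tests).
- **Closed-form denominator.** The curve is
  S(t) = [h(S₀−q) − q(S₀−h)e^{pt}] / [(S₀−q) − (S₀−h)e^{pt}]. This is the
  unique form satisfying S(0) = S₀ and S(∞) = q; it is evaluated
  internally with e^{−pt} so large p·t cannot overflow.

p is treated purely as the curve's rate constant (h⁻¹); no claim about
microbial growth rate is attached to it. A helper converts h⁻¹ to d⁻¹
(×24). q and h are reported with q the smaller root always; if the
root formulae assign them in the other order the values are swapped with
a warning.

Degenerate cases are errors, not fallbacks: K₂ = 0 (first-order law,
q and h undefined), negative discriminant (complex roots), coincident
roots, and S₀ outside (q, h]. S₀ = h exactly is allowed and yields a
constant curve — the natural description of an inactive control reactor.

## Fitting

`fit_series` minimises Σᵢ (Sᵢ − S(tᵢ))² over (p, q, h), with S₀ fixed to
the first observation by default (optionally free as a fourth parameter).
Optimisation runs in root space rather than coefficient space because the
bounds p > 0, 0 ≤ q < min(S), h ≥ max(S) encode model validity directly
and keep the search away from complex-root regions; coefficients are
recovered through the exact inverse map, so the reported (K₀, K₁, K₂) and
(p, q, h) are mutually consistent to machine precision. The solver is
SciPy's bounded trust-region-reflective least squares (the
bound-constrained member of the Levenberg–Marquardt family), ftol = xtol
= 10⁻¹⁰, ≤ 10⁴ evaluations, with up to 5 deterministic jittered restarts
(log-normal 25% jitter from a fixed seed) before failure is declared.

Starting values: q₀ = 0.5·min(S), h₀ = 1.02·max(S), and p₀ from the OLS
slope of ln[(S−q₀)/(h₀−S)] against −t over interior points, floored at
10⁻⁴ h⁻¹ (fallback 0.005 h⁻¹). On exact curves q₀ and h₀ land within a
factor of two of the truth; p₀ inherits the bias of the q₀/h₀ pivots and
can undershoot by up to ~3×, which is adequate for a starting point and
is corrected by the optimiser.

Goodness of fit R is the Pearson correlation between observed and fitted
concentrations (reported alongside R²; published per-reactor values such
as 0.94 and 0.40 sit on the R scale). R is undefined when either vector
has zero variance; a fit whose R falls below 0.7 is flagged
`good_fit=False` — accepted reactor fits sit at R ≥ 0.9 while a flat,
information-free control series lands near or below ~0.4. Standard
errors come from the Jacobian-based asymptotic covariance
s²(JᵀJ)⁻¹ with s² = SSE/(n−k), mapped to coefficient space by the delta
method.

## Treatment statistics

Removal is the signed percentage 100 − final·100/initial, computed from
the first and last observations; negative values mean net increase.
Fitted constants (typically K₁) are compared across treatments with a
Welch two-sample t statistic on the asymptotic estimates and standard
errors, Welch–Satterthwaite degrees of freedom with n−3 residual dof per
fit (n−4 when S₀ was free), two-sided p-values, α = 0.05 by default.
Pairwise comparisons can apply a Bonferroni-adjusted threshold; this is
off by default. Under the simulation null (two series regenerated from
the same truth at 2% noise and refitted), the measured rejection rate at
α = 0.05 is ≈ 0.08 over 500 replicates — mildly anticonservative, as
expected for asymptotic standard errors at 5 residual dof.

## Synthetic data

The generator emulates the two campaign designs: four reactors (A–D) on
the 7-point 0–504 h grid or the 8-point 0–360 h grid, parameterised by
default with the published per-reactor fits and measured initial
concentrations. Noise is additive Gaussian truncated at zero, SD
defaulting to 2% of each reactor's S₀ — the order of the reported
replicate scatter of the phenol assays (± ~6 mg/L on ~900 mg/L would be
smaller; 2% also covers sampling and handling variation). An optional
replicate count averages multiple noisy draws per time point. All
randomness flows from explicit seeds (per-reactor streams are spawned
from the design seed), so assays are exactly reproducible.

What the generator does **not** emulate: coupling between phenol and COD,
flocculant (lime) chemistry, community succession, autocorrelated or
heteroscedastic measurement error, and missing samples. Passing recovery
tests therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to real-data pathologies.

## Recovery study and its limits

`parameter_recovery_study` draws parameter sets uniformly over the union
of the published ranges (p ∈ [0.002, 0.035] h⁻¹, q ∈ [25, 235] mg/L,
S₀ ∈ [1000, 1350] mg/L, h = S₀·U(1.01, 1.15)), generates one noisy series
per draw on the 8-point grid and refits it. With the noise off, refitting
recovers (p, q, h) to better than 10⁻⁴ relative. At the campaign noise
level (2% of S₀ ≈ 20–27 mg/L) the medians over 50 draws are roughly 9%
for p, 3% for h, but ~25% for q: much of the published parameter range
has a lag occupying most of the sampling window, so the series never
approaches the q-plateau and q is informed only weakly; moreover the
noise SD is of the same order as the smallest q values. This is an
information limit of the design, not of the estimator — at 0.5% noise
all three medians drop below 5%.

## Numerical choices

- Time in hours, concentrations in mg/L throughout; rates reported in
  h⁻¹ with an explicit ×24 conversion to d⁻¹.
- Root-space tolerances: round-trip (p,q,h) ↔ (K₀,K₁,K₂) holds to 10⁻¹⁰
  relative and is property-tested.
- Report tables round percentages to 1 decimal and rates to 3 decimals at
  presentation only; stored values keep full precision.
- Problem sizes used by the test suite and the acceptance script — 20
  parameter sets for the ODE-oracle check, 50 recovery draws, 500 null
  replicates — are the sizes at which the binomial/median summaries are
  stable to the tolerances asserted.
- Missing concentrations in input tables are dropped with a logged
  warning; duplicate (reactor, analyte, time) rows are hard errors naming
  the file lines.

## Known limitations

- q is weakly identified whenever the sampling window ends well above the
  plateau (see the recovery study); its standard error from the Jacobian
  is then optimistic, and comparisons should rely on K₁ (the default)
  rather than q.
- The Welch test treats the two fits as independent normal estimates;
  with 7–8 points per series this is asymptotic at best.
- Published summary rows are reproduced from printed, rounded
  coefficients; derived q and h agree with their printed counterparts to
  ~2%, the propagation of that rounding. One published second-campaign
  row is internally inconsistent (its printed p does not equal the
  discriminant of its printed coefficients at 3-decimal rounding) and is
  excluded from exact-reproduction checks.
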