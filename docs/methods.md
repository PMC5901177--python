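# Methods

## Biochemical model and temperature scaling

The core is the Farquhar–von Caemmerer–Berry (FvCB) model of C3 leaf
photosynthesis with two limitations: Rubisco carboxylation
(`Ac = Vcmax (Ci − Γ*)/(Ci + Km)`, `Km = Kc (1 + O/Ko)`) and RuBP
regeneration (`Aj = J (Ci − Γ*)/(4Ci + 8Γ*)`); net assimilation is
`min(Ac, Aj) − Rd`. Ties go to the Rubisco branch, and for Ci at or
below the compensation point Γ* gross assimilation is zero, so
`A = −Rd`. Triose-phosphate-utilization limitation is not modelled:
over the 15–25 °C, ≤1200 ppm measurement window used here it is not
identifiable and would add a parameter the data cannot support.

Kinetic constants default to the Bernacchi in-vivo parameterization
(Kc25 = 404.9 µmol/mol, Ea 79 430 J/mol; Ko25 = 278.4 mmol/mol, Ea
36 380; Γ*25 = 42.75 µmol/mol, Ea 37 830; O = 210 mmol/mol), all
overridable through `KineticParams` or the pipeline config. Temperature
scaling uses the non-peaked Arrhenius form
`k25·exp[Ea (Tk − Tref)/(Tref R Tk)]` with R = 8.314 J mol⁻¹ K⁻¹. The
reference temperature is Tref = 298.15 K — 25 °C exactly — rather than a
rounded 298 K, because every base rate in the package is indexed "at
25 °C"; the difference is below 0.1% for typical activation energies but
the exact identity `f(25 °C) = k25` is worth having. Peaked
(deactivation) forms are deliberately excluded: all measurements sit
below the thermal optimum, where the extra parameters are
unidentifiable.

Electron transport J follows the non-rectangular hyperbola
`θJ² − (αI + Jmax)J + αI·Jmax = 0` (smaller root) with defaults
α = 0.24 mol e⁻ per mol photons, θ = 0.85, PAR = 1500 µmol m⁻² s⁻¹ —
the conventional defaults of FvCB fitting tools. At PAR 1500 the
hyperbola runs close to saturation, so the choice has little leverage on
fitted Jmax; a `saturating_light` switch sets J = Jmax exactly, which is
convenient for closed-form tests.

## Per-curve fitting and quality control

Each A/Ci curve is fitted at its own leaf temperature for (Vcmax, Jmax),
with the curve's measured dark respiration held fixed (never
co-estimated). The default method is bounded nonlinear least squares
(parameters in (0, 1000] µmol m⁻² s⁻¹), initialized from a bilinear
estimate. Convergence requires the solver's success flag, finite
standard errors, a well-conditioned Jacobian (condition number < 10⁸ on
JᵀJ) and an interior solution; otherwise the bilinear estimates are
reported and the method recorded as `bilinear`. Standard errors come
from the asymptotic covariance s²(JᵀJ)⁻¹.

The bilinear method, used both as initializer and fallback, linearizes
the two branches: gross assimilation A + Rd is regressed through the
origin on `(Ci − Γ*)/(Ci + Km)` over candidate low-Ci subsets and on
`(Ci − Γ*)/(4Ci + 8Γ*)` over the remainder, scanning every split by Ci
rank and keeping the partition with the lowest total SSE. The second
slope estimates J, inverted through the light response to Jmax. This is
the standard branch-wise linearization; no canonical definition exists,
so the operationalization is recorded here.

Quality control applies four boolean criteria: (1) max Ci < 700 ppm,
(2) no plateau at high Ci, (3) RMSE > 6 µmol m⁻² s⁻¹ over the fitted
points (RMSE = √(mean squared residual)), (4) bilinear method used. A
curve is excluded iff at least two hold. "No plateau" is
operationalized as an OLS slope of A on Ci above
0.005 µmol m⁻² s⁻¹ per µmol/mol over the three highest-Ci points; the
threshold, the point count and the other cutoffs are configurable.
Criterion 4 follows the method actually used, whatever the reason for
the fallback. Steady-state Anet, gs and D for design-level analyses are
taken from the last point whose Ca lies within ±5 µmol/mol of 400 ppm —
with the standard step sequence (400, 400, 300, 200, 100, 50, 400, 400,
600, 800, 1000, 1200) that is the 8th point.

## Group-level temperature responses

Per design cell (ecotype × treatment × garden), retained curves' Vcmax
and Jmax are fitted with the Arrhenius function in (k25, Ea) by
nonlinear least squares, seeded from the log-linear regression. Ea is
carried in J/mol internally and reported in kJ/mol. Fit summaries
follow nonlinear-regression conventions: model SE = √(SSE/(n−2)),
adjusted R², and an F statistic against the mean-only model with
(1, n−2) degrees of freedom. Confidence bands use the first-order delta
method on the (k25, Ea) covariance with a t quantile on n−2 df. All
observations at a single temperature raise an unidentifiability error;
fewer than three distinct temperatures is allowed but flagged.

Dark respiration per cell is fitted as `Rd = a exp(b Tleaf)` (Rd stored
as a positive magnitude), and `Q10 = exp(10b)` is attached as an exact
identity of the fitted b — an exponential model with constant Q10 is
appropriate over a 10 °C span below the respiratory optimum, where a
variable-Q10 form cannot be resolved. The Jmax(25):Vcmax(25) ratio is
computed per tussock from the 25 °C curve fits, analysed with a
three-way ANOVA, and pooled into an OLS regression of Jmax(25) on
Vcmax(25).

## Design statistics

Factorial ANOVAs are fixed-effects OLS fits with Type II sums of
squares — quality-control exclusions leave cells mildly unbalanced, and
Type II is invariant to that choice on balanced data (tested). Empty
design cells raise an error naming the cell rather than silently
dropping terms. Power transforms (1/y, y⁻², y⁻¹ᐟ²) are applied to the
response before fitting and recorded in every output row so transformed
means are never silently back-transformed. The outlier screen for leaf
nitrogen drops values more than 2 SD (sample SD of the full input) from
the mean in a single pass — survivors are not re-screened — and is
applied per garden only where configured. Stomatal regressions are
plain OLS of gs on D; a constant D is a singular design and raises.

## Synthetic data generator

The generator emulates the full campaign: 3 ecotypes × 2 treatments ×
5 tussocks × 3 leaf temperatures per garden = 90 curves per garden, plus
leaf-trait tables and hourly met series. Per-cell generating parameters
(Vcmax25 53.5–76.5 µmol m⁻² s⁻¹, Ea 42–57 kJ/mol, Jmax25 = 2.09·Vcmax25,
EaJ = 43 kJ/mol, Rd25 = 1.2 µmol m⁻² s⁻¹, Q10 1.23–1.70) are realistic
Arctic-sedge magnitudes spanning the design's warming gradient.
Tussock-level variation is multiplicative: CV 10% on Vcmax25, and 5%
scatter of Jmax25 about the cell ratio — the latter set so the pooled
ratio regression has R²adj ≈ 0.9, the strength of relationship the
design represents.

Physical consistency is enforced by construction: Ci is never sampled
but solved by bisection from the supply–demand balance
`A(Ci) = gc (Ca − Ci)` with a fixed per-curve CO₂ transfer conductance
(0.15 mol m⁻² s⁻¹, declining mildly with temperature), so every
(Ca, Ci, A) triplet lies on both curves and Ci can exceed Ca only when
the leaf is a net CO₂ source. Measurement noise is additive Gaussian on
A (σ = 0.5 µmol m⁻² s⁻¹) and multiplicative on measured Rd (σ = 10%).
Cuvette vapour pressure deficit centres on 1.0/1.3/1.9 kPa at
15/20/25 °C; stomatal conductance is drawn around per-ecotype gs–D
lines (e.g. −60.67·D + 232 mmol m⁻² s⁻¹ for CF) with noise sized to
leave R²adj near 0.1–0.15 — stomatal behaviour is weakly coupled to D
by design. Met series are a monthly baseline plus diurnal sinusoid plus
shared AR(1) weather noise, with OTC offsets of 1.8/1.9/1.0 °C (TL) and
0.8/0.6/0.3 °C (SAG) per month and monthly PAR attenuation fractions
for the chambers.

Randomness is split per entity (curve, tussock, trait row, met series)
by hashing stable string identifiers into independent `SeedSequence`
streams, so enlarging the design never reshuffles existing entities and
identical seeds give byte-identical outputs.

What the generator does *not* emulate: instrument drift and leaks,
within-curve serial correlation, stomatal patchiness, acclimation
trajectories over the season, or tussock demography. Passing
recovery tests therefore show the estimators are correct under the
stated noise model, not that field data of arbitrary quality will yield
unbiased parameters.

## Pipeline, numerics, determinism

`run_pipeline` executes fixed stages (load/simulate → fit+QC →
blacklist → Arrhenius → respiration → ratio → traits → Anet ANOVAs →
gs–D → met) and writes one CSV per surface plus a manifest (config
hash, seed, exclusion counts). The config hash covers the analysis
configuration but not the output path. All temperatures are °C at
interfaces; Kelvin exists only inside the Arrhenius expressions.
Degenerate inputs fail loudly with typed errors (schema, integrity,
unfittable, degenerate design), which the CLI maps to distinct exit
codes (2/3/4/5).

Problem sizes in the test suite and acceptance script — 100 seeded
curves for noisy recovery, 200 Monte-Carlo replicates for coverage, the
two-garden 180-curve pipeline — are the package's chosen verification
scale: large enough for stable rates, small enough to run routinely.

## Known limitations

- Mesophyll conductance is not modelled; fitted Vcmax is an apparent,
  Ci-based rate, as in most field studies.
- The bilinear fallback's standard errors are not reported (NaN): the
  split-selection step invalidates the usual OLS covariance.
- Coverage of ±2·SE intervals is the t-distribution's nominal ~93% at
  these group sizes, not 95%; confidence bands use the delta method and
  inherit its first-order accuracy.
- The monthly SE basis is the month's daily values (sensors averaged
  first); an hourly basis would give smaller SEs and is configurable in
  the code but not exposed in the pipeline config.
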