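# Methods

## Models and assumptions

**Ping-pong rate law.** The two-substrate steady-state model assumes a
substituted-enzyme mechanism: the cofactor (NADPH, by convention substrate
B, although the algebra is symmetric) reduces the enzyme-bound FMN and
leaves before the nitroaromatic or quinone substrate (A) binds and is
reduced. Its signature is that double-reciprocal plots of 1/v against 1/A
at different fixed B are parallel, with common slope K_mA/kcat; the
property suite asserts this numerically. Initial rates are assumed to be
true initial slopes — no substrate depletion, enzyme inactivation or
product inhibition — and measurement error is assumed roughly proportional
to the rate, which motivates the 3% multiplicative noise default of the
generator, but the fits themselves use unit weights by default (matching the
unweighted regression of the assay protocol); `weighting="relative"` on
the kinetic fits divides each residual by the observed rate instead.

**Mixed inhibition.** The inhibitor is allowed an independent dissociation
constant in each half-reaction, multiplying the corresponding Km term by
(1 + [I]/Ki). "No competition in this half" is encoded by the explicit
sentinel `NO_INHIBITION` (`math.inf`), which makes the factor exactly 1
for every inhibitor concentration rather than approximately 1 for a large
Ki. All series (each substrate varied at a fixed, near-saturating
co-substrate, at zero and two nonzero inhibitor levels) are refitted
simultaneously — nothing is frozen from the inhibitor-free fit.

**Nernst models.** Titration points are treated as equilibrium
measurements; no cell or mediator kinetics are modelled. The Nernst slopes
are fixed constants, 59 mV/decade per electron and 29.5 mV for the
concerted two-electron step, rather than recomputed from temperature, for
bit-compatibility with the published equations. The two-step expression is
implemented verbatim: the numerator term that grows with oxidising
potential carries E1. Under the usual couple naming (E1 =
semiquinone/hydroquinone, E2 = oxidised/semiquinone) those labels are
interchanged, so in this package's orientation a stabilised semiquinone
corresponds to E1 − E2 large and positive. With nearly equal potentials —
the regime of free NfsA — the distinction is immaterial.
`species_fractions_two_step` isolates the interpretive step of reading the
three denominator terms as relative populations ox : sq : red. Exponents
are clamped at ±300 decades, far outside any physical potential range, so
clamping never changes a result within fitting range but keeps optimizer
excursions finite.

## Fitting

All estimation is unweighted nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, ftol 1e−12,
xtol 1e−10). Strictly positive parameters (kcat, Km, Ki) are fitted as
logarithms; potentials in natural space; the semiquinone amplitude b in
natural space with a [0, 5] bound (it may legitimately be 0). Each fit
uses 8 starts: one data-driven heuristic (kcat₀ = max observed v/[E],
Km₀ = median concentration, E₀ = potential nearest half-signal) plus seven
seeded log-normal/normal perturbations of it; ties within 1e−9 in cost are
broken by the smaller parameter-vector norm so results are deterministic
given a seed. Standard errors come from the Gauss–Newton covariance
s²(JᵀJ)⁻¹ with the Jacobian transformed back to natural parameters;
per-parameter P values are two-sided t tests against zero on the residual
degrees of freedom. How the published per-parameter P values were obtained
is not stated anywhere we could rely on; the t-test convention here is the
common one in nonlinear-regression software and reproduces the reported
"<0.0001" pattern for well-determined parameters.

**Two-stage titration analysis.** Stage 1 estimates the fully oxidised and
fully reduced absorbances of each half-titration (grouped by replicate and
cycle). Each group is fitted with free endpoints under *both* candidate
models and the endpoints of the better-fitting one are adopted. Fitting
only the concerted model here, the simplest reading of the protocol, biases
the endpoints whenever the underlying curve is two-step-shaped; fitting
both makes stage 1 exact on noiseless data of either shape while remaining
faithful to the two-stage description, which names no stage-1 equation.
Endpoint uncertainty is carried forward only as the poorly-anchored
warning (scaled span < 0.5), not into stage-2 weights. Stage 2 scales every
point with its own cycle's endpoints, pools all cycles, and fits both
Nernst models to the pooled fractions.

**Model comparison.** Nested pairs (both-halves vs half-only inhibition)
use the extra-sum-of-squares F test,
F = ((RSS_r − RSS_f)/(df_r − df_f))/(RSS_f/df_f), preferring the full
model at p < α (default 0.05). The concerted model is not an exact
parameter restriction of the two-step model (the two-step curve only
approaches the 29.5 mV shape in the limit of widely split potentials), so
the primary verdict for that pair uses the small-sample corrected Akaike
criterion (k counts fitted parameters plus the variance), and the F test
treating the concerted model as two-parameters-fewer is reported alongside,
flagged approximate.

**Derived efficiency.** kcat/Km standard errors use first-order
propagation with the fitted kcat–Km covariance by default; a
covariance-free computation is available (flagged) and typically differs
by a few percent at these correlation levels. The propagated error is
validated against a 10 000-draw Monte-Carlo oracle in the test suite.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not the chemistry: rates are exact rate-law evaluations times enzyme
concentration times noise; titration absorbances are affine in the
oxidised fraction. Defaults, fixed once: 6×6 factorial grids at
{0.25, 0.5, 1, 2, 4, 8}×Km (the information-rich region around each
Michaelis constant; the original concentration grids are not published),
10 nM enzyme, 3% multiplicative Gaussian noise (consistent with the
few-percent standard errors of the published fits), inhibitor at
{0, Ki, 2.5 Ki} with the co-substrate fixed at 97 µM (NADPH) or 99 µM
(nitrofurazone) as in the inhibition experiment, titration endpoints
0.8/0.1 AU (arbitrary but recorded) on the down-then-up 20 mV schedule
(−50 → −350 mV, then −335, −320 → −90, −60 mV), and an additive 1e−4 AU
absorbance floor. No hysteresis between cycles, substrate depletion,
inner-filter effects or enzyme inactivation are simulated — so passing
recovery tests demonstrates estimator correctness and identifiability
under the assumed error model, not robustness to those real-data
pathologies.

## Degenerate inputs and numerical choices

Designs that cannot identify the requested parameters (a single
co-substrate level, no inhibitor-free series, fewer points than
parameters) raise `DesignDeficientError` before any optimisation.
Non-convergence is flagged on the result, never silent. A singular normal
matrix falls back to the pseudo-inverse. Zero-substrate rates are exactly
0; an SE of exactly 0 with a nonzero estimate reports p = 0 (degenerate).
Stage-1 endpoint fits bound the endpoints within twice the observed
absorbance span to keep extrapolation finite on partial titrations.

## Problem sizes

The recovery experiments in the acceptance script use the default designs:
36-point rate surfaces and 36-point inhibition datasets (12 conditions ×
3 inhibitor levels), 10 seeds each, and 30-point two-cycle titrations —
the same order of magnitude as the underlying experiments, and enough for
mean recovered parameters to sit within a few percent of truth at 3%
noise.

## Known limitations

Enzyme concentration is taken as supplied; whether rates are per active
site or per dimer is the caller's convention and nothing in the package
resolves that ambiguity. Apparent single-substrate parameters are only
meaningful at the fixed co-substrate concentration used. The E1/E2 label
orientation discussed above matters only when the two potentials are well
separated. No bootstrap or Bayesian uncertainty is provided; Monte-Carlo
propagation exists only as a test oracle.
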