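# Methods

## The speciation model

Unconjugated bilirubin (UCB) is treated as a diprotic acid with
conditional ionization constants pKa₁ (H₂B → HB⁻) and pKa₂ (HB⁻ → B⁼).
The two monoanion tautomers are lumped into a single HB⁻ species, as in
the solvent-partition formalism the constants come from.  Fractions of
the unbound monomeric pool are

    f_H₂B = 1/D,  f_HB⁻ = x/D,  f_B⁼ = y/D,
    x = 10^(pH−pKa₁),  y = 10^(2pH−pKa₁−pKa₂),  D = 1 + x + y.

Two pKa parameterizations are shipped: the solvent-partition pair
(8.12, 8.44), which the package treats as the physically supported
default, and the low literature pair (4.2, 4.9), retained because the
package's central scientific use is demonstrating that the low pair is
incompatible with binding-vs-pH data.  Ionic strength and temperature
are not modeled; every constant is conditional on the medium in which it
was fitted.  All concentrations are µM and all logs base 10, matching
the units in which every shipped constant is quoted.

### Dianion dimerization

Self-association of the dianion, 2 B⁼ ⇌ (B⁼)₂ with K_D = 0.26 µM⁻¹, is
the only oligomer carried.  The mass balance counts a dimer as two
monomer units:

    total = c_H₂B·D + 2·K_D·c_B⁼²,   c_B⁼ = y·c_H₂B.

This is a quadratic in c_B⁼, solved with the stable q-form
c_B⁼ = 2·total/(b + √(b² + 8·K_D·total)), b = D/y, which avoids
cancellation when K_D·c_B⁼ ≪ 1.  The exact algebraic form of the
original mass-balance equation is cited in the source literature but not
reprinted; the form above is validated by a forward-then-invert
round-trip oracle (compose a composition, total it, decompose; agreement
to 1e−9 µM) and by reproducing all downstream anchor numbers.  The
dimerization constant belongs to the high-pKa framework; low-pKa
counterfactual fits therefore use K_D = 0 (see the vesicle section).

### Solubility and supersaturation

With the diacid pinned at its aqueous solubility S_H₂B = 0.051 µM, the
total monomeric solubility is St(pH) = S_H₂B·(1 + 10^(pH−pKa₁) +
10^(2pH−ΣpKa)).  The dianion term uses the pKa *sum* (16.56), which is
determined more precisely than the individual constants; the monoanion
term uses pKa₁.  The saturated free-dianion concentration is
[B⁼]sat = S_H₂B·10^(2pH−ΣpKa).  The supersaturation ratio R = B_f/St
flags metastable solutions (R > 1); the package models supersaturated
states as simple equilibria of the stated free concentration and leaves
aggregation/precipitation kinetics out of scope.

## Binding and midpoints

A pH-insensitive host binding one species with distribution ratio
K = mols bound/mols free gives F(pH) = K·f/(K·f+1).  The titration
midpoint is defined as F = F_peak/2 with F_peak the maximum of F over
pH.  For diacid- and dianion-binding hosts f approaches 1, so
F_peak = K/(K+1) and the midpoint condition reduces to f = 1/(K+2),
solved in closed form as a quadratic in 10^pH and cross-checked by
bisection (agreement ~1e−10).  For a monoanion-binding host, whose
fraction peaks below 1 at f_peak = 1/(1+2√(K₂/K₁)), the general
condition f = f_peak/(K·f_peak+2) applies and the ascending (low-pH)
branch is reported.

This half-of-maximum definition reproduces the reference midpoint
series to within 0.01 pH (the reference values carry a consistent
+0.004…+0.010 offset against the exact closed-form roots, consistent
with grid-based evaluation in the original analysis), **except** the
diacid-host values quoted for K = 1 (8.255) and K = 10 (8.780), for
which the closed form gives 8.217 and 8.707.  Whatever definition
produced those two numbers is not recoverable; they are excluded from
the reproduction battery.

## Phosphatidylcholine vesicles

Model: ñ = K″·[H₂B]_f, with ñ mol UCB bound per mol total PC (defaults:
10 µM UCB, 100 µM PC).  [H₂B]_f comes from the unbound pool
B_f = B_t − ñ·PC via the monomer/dimer balance, assuming the unbound
pool speciates as it would without PC present.  K″ is estimated as the
mean of per-point ratios ñᵢ/[H₂B]_f,ᵢ with its sample SD — the estimator
whose reported form ("mean ± SD") the original constant carries — rather
than least squares.  The quoted correlation r is the Pearson correlation
between observed ñ and the self-consistent model curve evaluated at the
data pH values.  Forward prediction solves ñ = K″·[H₂B]_f(B_t − ñ·PC)
by bracketed root-finding on [0, B_t/PC]; the root is unique because the
right side decreases in ñ.

Counterfactuals: (i) at strict equilibrium saturation [H₂B]_f is pinned
at S_H₂B, so ñ is flat at its anchor value — the observed decline with
pH therefore implies the free phase was supersaturated; (ii) under pKa
4.2/4.9 the anchor point (pH 6.54, ñ = 0.049, B_f = 5.1 µM) holds only
~0.52 nM diacid, demanding K″ ≈ 94 µM⁻¹, and the resulting curve
collapses within half a pH unit.  The low-pKa anchor calculation omits
the dimer (K_D = 0): the dimerization constant was fitted within the
high-pKa framework and applying it to a low-pKa speciation (where the
dianion dominates at µM levels) would be internally inconsistent — and
it is the no-dimer form that reproduces the quoted 94 µM⁻¹.

The nine figure-digitized (pH, ñ) observations behind the published
K″ = 0.00932 ± 0.00053 µM⁻¹ are not printed anywhere and are not
shipped; that constant is a configuration default exercised by synthetic
round trips, not refit.

## β-cyclodextrin

Signal model Δε = Q·[B⁼]_f with Q = 1.099 per µM (a shipped default; the
underlying CD readings are not printed, so Q is not refit — a
through-origin fit operation is provided for synthetic data).  The bound
amount is proportional to [B⁼]_f, with the proportionality fixed by the
pH-10.8 anchor: an affinity constant of 23 L/mol against 10 mM host
binds 18.7% (4.67 µM) of 25 µM total UCB.  At each pH the bound amount
is solved self-consistently with the free-pool speciation by bracketed
root-finding on [0, total].  Host depletion is ignored (≤ 0.25% cavity
occupancy).  The discriminating property: under the high pKa pair
Δε(6.5)/Δε(10.8) < 0.05, while under the low pair Δε(7.0)/Δε(10.8) > 0.9
— only the former matches the observed sigmoid.  The saturated scenario
caps [B⁼] at [B⁼]sat(pH), taking the minimum with the supersaturated
prediction so the cap is inactive where the solution is undersaturated.

## Taurocholate micelles

Each species partitions independently with micelle/water ratios
K_H₂B = 1.41, K_HB⁻ = 12.9, K_B⁼ = 730 (50 mM taurocholate).  Fractions
of total UCB bound as each species:

    fˢᵢ = Kᵢ·wᵢ / T,  w = (1, x, y),  T = Σ (1+Kᵢ)·wᵢ.

Apparent pKa's follow from ratios of *adjacent* species' distribution
ratios, pKa_app = pKa_aq + log₁₀(K_up/K_down) — validated against all
three quoted values (7.16, 6.69, sum 13.85) and against a bracketing
oracle (the pH where equal amounts are bound as HB⁻ and B⁼ equals the
apparent pKa₂ to 1e−6).  The additive (1+K) form does not reproduce the
quoted shifts and is not used.

The chloroform→aqueous partition profile is implemented as
log₁₀P = log₁₀P₀ − log₁₀(1 + 10^(pH−A) + 10^(2pH−B)), A = 7.36,
B = 14.08.  **Note:** the source prints this equation without the
logarithm on the bracket, which is dimensionally inconsistent; the
−log₁₀ form is the one consistent with the solvent-partition formalism
and with partition decreasing monotonically with pH.  P₀ is never
quoted, so the profile is exercised only in relative/limit form.

CD model: 10³θ = A*·fˢ_HB⁻ + B*·fˢ_B⁼, fitted by no-intercept least
squares to the packaged seven-point reference table (readings at 4.6 µM
already scaled ×34/4.6 to the 34 µM basis).  Conventions — r as the
Pearson correlation of observed vs fitted, residual SD with an n−p
denominator, standard errors from sd²(XᵀX)⁻¹ — were fixed because they
reproduce the full quoted fit (A* = −98.7 ± 5.6, B* = 5.24 ± 0.54,
r = 0.992, SD = 1.1).  Two caveats about the reference table itself: its
"calculated θ" column is consistent with B* ≈ 5.14 rather than the
fitted 5.24 and is retained for reference only, never as an oracle; and
its fˢ_B⁼ column disagrees with the distribution-ratio formula by up to
4e−4 at three pH values (the formula gives 0.5794/0.9553/0.9574 where
the table prints 0.5790/0.9550/0.9570), consistent with rounded
intermediates in the original computation.  The affected acceptance
check is left failing at its 1e−4 tolerance rather than widened; the
fˢ_HB⁻ column matches at all seven pH values.

## Synthetic data

Generators evaluate the deterministic model curve of one stage on a pH
grid (restricted to [4, 12]) and add independent Gaussian noise, seeded
via `numpy.random.default_rng` — pure functions of (parameters, seed).
No error model is quoted for the original data, so Gaussian noise is
assumed with SD defaults matching the residual scales of the
corresponding fits: 0.002 on ñ, 1.1 on 10³θ, and 5% of the plateau
signal for Δε.  Vesicle ñ is clipped only at its upper physical bound
B_t/PC (beyond which the free pool would be negative); small *negative*
noisy readings are deliberately kept, because where the model curve
falls below the noise floor (ñ ~ 1e−4 above pH 9 at the default K″),
truncating at zero would bias the mean-of-ratios estimator upward by
roughly the half-normal mean of the noise and parameter recovery would
fail.  With negative readings kept, the estimator is unbiased and the
200-replicate recovery experiment centers on the generating K″.

What the generators emulate — and what they do not: they reproduce the
grid sizes, signal magnitudes and noise scales of the corresponding
published titrations, but real data additionally carry time-dependent
aggregation/precipitation drift, pH-measurement error, and
concentration-scaling error between runs, none of which is simulated.
Passing recovery tests therefore demonstrate estimator correctness under
the stated noise model, not robustness to those systematics.

## Numerical choices

- Quadratics are solved in the q-form to avoid cancellation; closed-form
  midpoints are cross-checked by `scipy.optimize.brentq` on a bracket of
  pH −5…25 (xtol 1e−12).
- Rounding (4 d.p. for fractions, 3 d.p. for µM solubilities) lives only
  in presentation code; all computation is double precision throughout.
- Degenerate inputs raise typed errors: `ValidationError` (CLI exit 2)
  for out-of-domain values, malformed tables and unsorted grids;
  `NumericalError` (CLI exit 3) for rank-deficient designs and failed
  brackets.
- The no-intercept least-squares solver refuses rank-deficient designs
  rather than returning a minimum-norm solution, since collinear
  bound-fraction columns (e.g. a single-pH design) leave the
  coefficients unidentified.

## Problem sizes

The reproduction battery (61 checks) and the full test suite run in a
few seconds.  Monte-Carlo experiments use 200 replicates for the vesicle
K″ recovery and the taurocholate coefficient-spread check, and 30 for
the cyclodextrin Q recovery — enough for the standard-error comparisons
they make while keeping the suite fast.

## Known limitations

- Conditional constants only: no activity corrections, no temperature
  dependence, no oligomers beyond the B⁼ dimer.
- The vesicle and cyclodextrin proportionality constants (K″ = 0.00932
  µM⁻¹, Q = 1.099) are shipped defaults, not refit, because their
  underlying data points are not printed anywhere accessible.
- Binding treats one species per host; the taurocholate module is the
  only multi-species stage, and it assumes independent partition of each
  species with no micelle-composition effects.
- Supersaturated states are modeled as static; the kinetics of
  aggregation and precipitation that relieve supersaturation are out of
  scope.
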