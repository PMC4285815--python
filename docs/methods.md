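# Methods

## Model

Phenotypes are points **z** ∈ ℝⁿ under Gaussian stabilizing selection toward
a linearly moving optimum z_opt(t) = **v** t:

    w(z, t) = exp( -½ (z − v t)′ Σ⁻¹ (z − v t) ),

with Σ (the selection matrix) and M (the covariance of new mutational
effects) symmetric positive definite. Every mutation affects every trait
(universal pleiotropy, continuum of alleles). Environmental variance is not
modeled separately; it can be regarded as absorbed into Σ. The half-quadratic
exponent convention above is fixed throughout; with it, the scaled rate of
environmental change

    γ = v₁* δ̄² / (Θ m̄³)

(canonical coordinates; δ̄² and m̄² are the geometric-mean eigenvalues of Σ
and M) reproduces both reference anchors of the standard scenarios:
γ = 10⁻⁴ at (n = 2, v₁ = 10⁻⁵, Θ = 1, σ² = 10, m² = 1) and γ/v₁ = 10 for any
speed at those scales. Any alternative convention must be checked against
both anchors jointly; this pair is self-consistent.

When comparing dimensions n we hold the per-trait mutational distribution
fixed (Euclidean superposition): adding traits does not change m², so the
total effect of a mutation grows with n.

### Selection coefficients and their linearization

The exact selection coefficient of mutant x against wild type y is
s = w(x,t)/w(y,t) − 1. For the Gaussian landscape the *log*-fitness
difference is exactly linear in time,

    ln w(x,t) − ln w(y,t) = λ (t − τ),
    λ = v′ Σ⁻¹ (x − y),   τ = (x′Σ⁻¹x − y′Σ⁻¹y) / (2λ),

because the quadratic t² terms cancel. λ is the rate of change of s and τ the
lag time at which the mutant becomes neutral; when λ = 0 the sign of s never
changes and τ is reported as +∞ with an explicit flag, so integrators can
branch without exception handling. The linearized s is used inside the
semi-analytic machinery (where the derivation assumes it); the exact s is
used for acceptance decisions in the walk engine and is available as an
option in the analytics for sensitivity checks. First-order agreement
|s_exact − s_lin| ≤ s_lin² holds whenever |s_lin| < 0.1.

### Isotropizing transform

Any model can be reduced to isotropic selection with movement along the
positive first axis: whiten by Σ^(−1/2) (symmetric eigendecomposition-based
root; eigenvalues below 10⁻¹² of the largest raise a validation error rather
than being silently regularized), rotate the transformed velocity onto e₁,
and rescale uniformly so the transformed M has m̄² = 1, leaving
Σ* = (δ̄²/m̄²) I. The rotation is a deterministic Householder reflection with
the sign of the last axis flipped to restore det +1: an orientation-reversing
map would silently flip what "above the optimum's track" means, corrupting
the kite-effect diagnostics. Fitness is exactly invariant under the
transform, hence so are selection coefficients, acceptance decisions, and γ.
The transform is idempotent on canonical models, and a walk simulated in
canonical coordinates from the same underlying standard-normal draws (via
the `mutation_chol` hook) reproduces the original walk exactly with effects
mapped through the transform.

## Adaptive-walk engine

The walk approximation treats fixation as decided immediately at a
mutation's appearance and instantaneous thereafter: proposals arrive as a
homogeneous Poisson process at rate Θ/2 on a continuous clock (no
per-generation discretization — the exponential-waiting-time algorithm is
exact for a homogeneous proposal process with state-dependent thinning),
effects are drawn MVN(0, M), and a proposal at time t is accepted with
p_fix(s). Two p_fix modes: `linear` (2s clamped to [0,1] — the clamp is
required in fast-optimum regimes where s is not small) and `exp`
(1 − e^(−2s)); both return 0 for s ≤ 0, neglecting chance fixation of
deleterious mutations. Refinements that track the change of s *during* the
fixation process are deliberately not implemented; within the walk framework
they do not improve accuracy. The log-fitness ratio is capped at 700 before
exponentiation; any proposal beyond that cap is accepted with probability 1
in either mode, so the cap is unobservable in results.

Proposals are generated in batches whose size doubles (1024 → 131072) while
no acceptance occurs, which keeps slow regimes (10⁴–10⁵ proposals per
substitution) tractable in vectorized numpy. Results are exactly
reproducible given a seed; replicate seeds in ensembles are spawned from the
master seed via `numpy.random.SeedSequence`. An optional extinction proxy
terminates a walk when wild-type fitness falls below a configurable
threshold (off by default; any particular threshold is arbitrary).

## Semi-analytic step distribution

With wild type y at t = 0, substitutions form an inhomogeneous Poisson
process with rate

    g(t, y) = Θ ∫_χ p(α) s₊(y+α, y, t) dα,

where χ is the beneficial set. Under the linearized s, χ is the interior of
an ellipsoid: in whitened coordinates w = Σ^(−1/2)(α − b) with b = v t − y,
s_lin = (R² − |w|²)/2 and χ = {|w| < R}, R² = b′Σ⁻¹b. Integrals over χ use
product Gauss–Legendre quadrature (radial × angular; trapezoid in the
periodic angle) for n ≤ 3 and uniform-in-ball Monte Carlo with an explicit
seed for larger n. The survival function F(t|y) = exp(−∫₀ᵗ g) is
precomputed on a grid extending until F < 10⁻¹⁰ (bracketing by doubling,
then cumulative trapezoids on 2049 points); v = 0 with y at the optimum is
handled as the exact F ≡ 1.

The unconditional density of the next step is computed by two algebraically
equivalent but numerically independent routes — integrating the normalized
conditional density ψ(α|y,t) = Θ p(α) s₊ / g(t,y) against the waiting-time
density f = g·F, and the per-α lag-time form Θ p(α) ∫ λ(t−τ)₊ F(t) dt —
whose pointwise agreement (≤10⁻³ relative on a 21×21 grid in the reference
scenario) is a standing consistency check.

### Slow-regime (uniform) approximation

When the optimum moves slowly, all beneficial mutations are small and p(α)
can be flattened to an improper uniform density of height
p₀ = (2π)^(−n/2) det(M)^(−1/2); every integral against it is over the
bounded set χ and therefore finite. From the ball geometry, the closed-form
rate is g(t) = Θ p₀ Vₙ r^(n+2) / (σ²(n+2)) with r = v₁t and Vₙ the unit-ball
volume, giving F(t) = exp(−c t^(n+3)). Conditional on a step at time t the
step is distributed on the ball with density ∝ (r² − |u|²), whence
E[α₁|t] = r and Var(α₁|t) = Var(α_⊥|t) = r²/(n+4). First-step moments follow
by one-dimensional quadrature of the waiting-time density (the Γ-function
closed forms this implies are validated numerically in the tests against
dense brute-force integration rather than transcribed). Two consequences are
used as checks: the coefficient of variation of α₁ depends only on n, and
the mean step grows with both γ and n. A runtime warning is raised when the
predicted mean step exceeds the mean mutational standard deviation, where
the flat-density assumption degrades; at γ ≤ 10⁻⁴ the approximation is
accurate to well under 5% for the mean.

## Individual-based engine

Diploid individuals carry L unlinked additive loci; alleles are effect
vectors forming a per-locus mutational genealogy. Discrete, nonoverlapping
generations: (1) viability selection — death with probability 1 − w(z, t);
(2) regulation — random culling to carrying capacity K; (3) reproduction —
survivors randomly paired (no sexes, monogamous pairs; one survivor is left
unpaired when the count is odd, an O(1/K) effect), each pair producing
exactly B offspring with free recombination between loci and mutation with
probability u/2 per gamete per locus (rate u per diploid locus), the mutant
adding an MVN(0, M) deviate to the copied parental effect. Extinction is
fewer than 2 survivors, signaled as a terminal event. With B = 4 this life
cycle makes the effective size exceed the adult census (brood-size variance
below Poisson), N_e = (4/3) N, which the neutral test recovers from the
decay rate of heterozygosity.

Θ accounting: the reported supply is Θ = 2NLu with N the post-reproduction
census B·⌊K/2⌋ (N = 2K for B = 4), under which the standard configuration
K = 1000, L = 10, u = 5×10⁻⁶ reports Θ = 0.2. This is the only convention
consistent with that printed configuration; the alternative N = K (giving
0.1) is available as `convention="carrying_capacity"` and documented in the
function's docstring, since the choice is the single most consequential
bookkeeping ambiguity when matching walk and individual-based runs at equal
γ.

A substitution is recorded whenever the root of a locus's allele tree
changes, i.e. when the live alleles acquire a new most recent common
ancestor — equivalent to an allele (or its descendants) having taken over
the population. The production detector tracks the root incrementally,
pruning extinct subtrees (extinct lineages can never revive, so pruning is
permanent) and advancing the root while it has no live copies and a single
surviving child subtree, one substitution per edge. An independent
brute-force oracle recomputes the MRCA from the raw parent pointers every
generation; the test suite requires exact event-stream equality between the
two on randomized small runs.

## Diagnostics

"Direction of the optimum" and "orthogonal directions" are defined in
canonical coordinates (raw inputs are transformed first). Step correlation
is the Pearson correlation of (α₁, α₂) over fixed steps, flagged degenerate
below 3 steps or at zero variance. Kite lag is the time-average of the mean
phenotype minus the optimum over the stationary phase; by default the first
20% of a series is discarded as burn-in (the exact averaging window is a
package choice — the reference analyses contrast "first step" versus "entire
walk" but fix no burn-in). The deterministic reference dynamic is the
canonical equation dz̄/dt = c·M·Σ⁻¹(z_opt(t) − z̄), integrated with LSODA
(rtol 10⁻¹⁰; the system is linear and can be stiff for strong correlations);
its equilibrium lag solves c·M·Σ⁻¹·lag = v and the ODE endpoint is required
to match that linear solve to 10⁻⁶ relative after ≥50 relaxation times. The
empirical G-matrix is the population (ddof = 0) covariance of individual
phenotypes; in tests it is time-averaged across generations because a
single-generation snapshot during a sweep is dominated by that sweep.
Modality of effect-size and fitness-effect distributions is diagnosed with a
Silverman-bandwidth Gaussian KDE; an "interior mode" means the density
argmax lies above the lowest decile of the observed range (the underlying
claim is qualitative).

## Problem sizes and tolerances

Simulation sizes are chosen so the full suite exercises every claim at
meaningful statistical power while staying lightweight: 10⁴ replicate first
steps for the analytic-versus-walk comparison (3 Monte-Carlo standard
errors), 2000 replicates per cell for monotonicity sweeps over
γ ∈ {10⁻⁵, 10⁻⁴, 10⁻³} and n ∈ {1, 2, 4, 8} (whole-walk statistics pool the
first 5 steps of each replicate), 2000 pooled steps per speed for the
correlation regime switch, 12 × 400 neutral generations at K = 1000 for the
effective-size regression (10% tolerance), and 20 randomized 200-generation
runs at K = 40 for detector equivalence. Headline reference analyses in the
literature use 10⁴ walks per panel and individual-based runs to 10³
substitutions; the qualitative sign, monotonicity, and agreement properties
checked here are scale-free, and point comparisons carry Monte-Carlo
standard errors.

## What the generators do and do not emulate

The walk engine realizes the model's own idealization (monomorphic
population, instantaneous fixation): passing tests validate internal
consistency of theory and simulation, not the idealization itself. The
individual-based engine relaxes it — cosegregation, drift, demographic
stochasticity and extinction are real there — but still assumes free
recombination, no dominance, no environmental variance, no overlapping
generations, and equal mutation rates across loci. Linked-loci
(Hill–Robertson) variants, adaptation from standing variation, and
time-varying Σ, M, or stochastic optimum motion are out of scope. Real data
would additionally feature non-Gaussian mutational kernels, modular rather
than universal pleiotropy, and fluctuating environments, so quantitative
transfer of any particular number to data is not implied.

## Known limitations

* Grid-based step densities are implemented for n ≤ 2 (pointwise routes and
  moments for n ≤ 3 by quadrature; Monte Carlo beyond).
* The walk engine's RNG stream depends on its internal batch schedule;
  determinism is guaranteed per seed for a given package version, not across
  alternative proposal-loop implementations.
* The Θ convention ties walk and individual-based comparisons together; runs
  at different B require rematching γ.
* Substitution detection requires a single founder lineage per locus;
  neutral multi-founder experiments disable it (they measure drift, not
  substitutions).
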