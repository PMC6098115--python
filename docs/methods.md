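# Methods

## The model class

`linmap` treats stochastic gene-regulatory networks whose only nonlinear
(second-order) reactions are protein–promoter binding events.  The basic
object is an auto-regulatory feedback loop: a promoter switches between an
unbound state G and a bound state G\*, producing protein at rate ρ_u in G and
ρ_b in G\*; binding `cp·P + G → G*` has rate constant σ_b, unbinding
`G* → G + cp·P` has rate σ_u, and protein decays at rate 1.  All rates are
dimensionless — time is measured in units of the protein lifetime, so every
rate is the physical rate divided by the protein decay rate k_d.  Binding
sequesters the bound protein copies and unbinding releases them (reversible
binding); this convention is required for the exactness of the method under
detailed balance (ρ_u = ρ_b, where the protein law is Poisson(ρ)).

Variants share the same promoter logic: geometric production bursts
ψ(m) = b^m/(1+b)^(m+1) with mean b (the fast-mRNA limit; `burst_mean = 0`
means plain single-protein production — the degenerate m≡0 geometric is
useless), cooperative binding of cp ≥ 2 proteins, sinusoidal transcription
modulation ℓ(t) = 1 + Am·cos(kπt) with 0 ≤ Am < 1 so the production rate
stays positive, a two-gene mutual-repression toggle switch, a loop with
Michaelis–Menten protein decay (total-rate propensity k_d·n/(n+K); the
per-capita alternative is isolated behind the propensity-kind abstraction),
and a loop with explicit mRNA and translation.

## The linear mapping

The chemical master equation (CME) of these networks is intractable because
of the binding reaction.  The linear-mapping approximation (LMA) replaces
each binding reaction by a first-order promoter switch `G → G*` whose rate
is the conditional mean of the stochastic rate given an unbound promoter:

    σ̄_b(t) = σ_b · ⟨n_p(n_p−1)⋯(n_p−cp+1) | n_g = 1⟩,

a conditional mean-field closure.  Feeding σ̄_b back into the (closed)
moment equations of the mapped linear network gives a small nonlinear ODE
system; its solution yields the instantaneous effective rate σ̄_b(t′).  For
finite-time distributions the constant rate used in the linear solution is
the running time average σ̄_b*(t) = (1/t)∫₀ᵗ σ̄_b dt′ — equivalent to
truncating the Magnus expansion of the time-ordered propagator at its first
term.  The truncation error is bounded in time and first order in σ_b, so
the approximation degrades as the binding rate (the degree of nonlinearity)
grows and as |ρ_u − ρ_b| grows; at ρ_u = ρ_b it is exact.  In steady state
no averaging is needed and the closure collapses to algebra: a closed
quadratic form for cp = 1 (with ρ replaced by ρ·b in the bursty case) and
the unique nonnegative root of a low-order polynomial for cp ≥ 2, found by
bracketed bisection rather than closed-form cubic roots (avoids branch
selection; uniqueness is asserted numerically on every call).

The mapped linear network is the telegraph model, solved in closed form by
generating functions: with w = z − 1, ρ_Δ = ρ_b − ρ_u and
Σ = σ_u + σ̄_b + 1, the generating functions are products of exponentials
and Kummer confluent hypergeometric functions M(a, b, −ρ_Δ w).  The pmf is
the Taylor coefficient sequence about w = −1.

### Oscillatory driving

The time average is applied to the *effective switching rate only*.  The
sinusoidal production modulation is first-order and keeps the mapped
network exactly solvable, so the linear CME is propagated with the
modulation exact in time.  (Averaging the modulation as well inflates the
snapshot error several-fold and destroys the high-frequency accuracy.)
Consequence of the averaged switch: the predicted amplitude of mean-protein
oscillations decreases monotonically with driving frequency — the method
cannot resonate — while the deterministic rate equations do show the
resonance peak.

### Toggle switch, Michaelis–Menten decay, mRNA–protein loop

The toggle switch decouples under the mapping into two independent
telegraph genes; each gene's effective switching rate conditions on the
*other* protein's conditional mean, and the coupled closure is integrated
as one joint ODE system (no alternating fixed-point loop).  The
Michaelis–Menten decay keeps the mapped network nonlinear in the protein
count, so the closure is realized as a damped fixed-point iteration over
exact truncated-CME solves of the mapped network.  For the mRNA–protein
loop the mapped network is three-stage gene expression: the mRNA marginal
is a telegraph distribution in units of the mRNA lifetime, and protein
statistics are delivered at moment level (no closed-form protein marginal
is known for that linear network); moments up to fourth order agree with
simulation at the percent level.

## Numerics

* **Moment systems** are assembled by a generic polynomial engine over a
  monomial basis (gene indicators idempotent, g^k = g); for linear networks
  the hierarchy closes at any order.  The closure ODEs are integrated with
  BDF at rtol 1e-8 / atol 1e-10 (σ_b spans several orders of magnitude, so
  slow promoters make the system stiff).  σ̄_b is clipped at zero: solver
  transients can produce tiny negative conditional moments and a CME rate
  must be nonnegative.  The running time average uses the trapezoid rule on
  ≥ 2000 points of the dense solver output.
* **Coefficient extraction** samples the generating function on the circle
  |z| = 1 at M = 4N points and applies a discrete Fourier transform in
  50-digit mpmath arithmetic (conjugate symmetry halves the evaluations;
  roots of unity are precomputed).  Repeated symbolic differentiation of
  Kummer products in double precision is numerically hopeless beyond a few
  tens of coefficients.  Kummer functions are evaluated by `mpmath.hyp1f1`,
  which handles large negative arguments internally.  Aliasing folds tail
  mass beyond the sampling order back onto the support, so the truncation N
  defaults to mean + 12 sd of the matching moment solution.  The branch
  powers (−ρ_Δ w)^{±(Σ−1)} in the finite-time solution cancel analytically
  and are never evaluated.  The measure-zero parameter pole where
  2 − Σ is a nonpositive integer is avoided by a 3e-9 nudge of σ̄_b.
* **Truncated CME**: the generator is assembled sparsely over
  (gene modes) × (counts ≤ N); probability flux past the boundary is
  dropped and monitored as a defect (finite-state-projection semantics),
  and N grows geometrically until the boundary mass falls below 1e-10.
  Steady states come from a sparse LU solve with one row replaced by the
  normalization constraint (robust near bistability); transients use
  Krylov `expm_multiply`, or an explicit time-stepped propagation when the
  modulation is kept exact.  Geometric burst rows truncate the jump kernel
  at tail mass 1e-12.
* **Stochastic simulation** uses the Gillespie direct method in a
  numba-compiled kernel; per-realization seeds derive from a
  `SeedSequence`, making runs bitwise reproducible.  Time-modulated
  propensities use stepwise-constant sub-stepping with
  Δt ≤ 0.01/(kπ·Am + 1).
* **First passage**: before the first G → G* switch the reactions
  involving G\* cannot fire, so the closure runs with ρ_b = σ_u = 0 and
  deterministic initial moments of n0 proteins.  The survival is
  P0(t) = ⟨n_g⟩(t) = exp(−∫σ̄_b), a consistency the tests verify two ways.
  Defective cases (never switching, e.g. ρ_u = 0 with n0 = 0) report the
  defect explicitly rather than renormalizing.  The mean uses an
  exponential tail correction beyond the integration horizon.
* **Mean-FPT power laws** are least-squares slopes of log τ against the
  log-parameter over nine-point log-spaced grids.  The default decades are
  anchored at the canonical first-passage parameter point: σ_b ∈ [0.01, 0.1]
  at ρ_u = 60, and ρ_u ∈ [10, 100] at σ_b = 0.01.  For cp = 1 the reduced
  closure makes τ a function of the product σ_b·ρ_u alone, so the local
  log-log slope drifts from −1 (rare-switching limit) to −1/2
  (fast-switching limit); the quoted exponents −3/5 and −4/5 are properties
  of these decades, and the fit reports R² and warns when the quadratic
  log-log curvature exceeds 5% of the slope.
* **Sensitivity** of CV² uses central differences on log-parameters with
  relative step 1e-4, with CV² computed at moment level from the mapped
  network (identical to the distribution-level value for linear networks).
* **Modality** counts strict local maxima after filtering: peaks below
  1e-6 probability are ignored and peaks separated by a dip shallower than
  1e-6 (absolute) are merged; both thresholds are exposed.  The boundary
  n = 0 counts when P(0) > P(1).
* **Λ (time-scale ratio)** is |λ_gene|/|λ_protein| of the 2×2 Jacobian of
  the deterministic rate equations at their fixed point, the protein
  eigenvalue being the one closer to −1 (the nondimensional decay rate).

## Problem sizes and what the tests show

Stochastic comparisons run at 15–20k Gillespie realizations (per-bin
sampling error about 4% at bin probability 0.01, twice the error of an
80k-realization run) against snapshots at t ∈ {1, 5, 10, 20}; bifurcation
scans use 10×10 surrogate grids over (σ_b, σ_u) — the published heatmap
axis ranges are not printed, so the tests check orderings and the
smallness of LMA/reference disagreement rather than absolute bimodal-area
percentages.  The sensitivity dominance check runs on a coarse sub-lattice
of the ρ ∈ [1, 100], σ ∈ [0.01, 1] box.  All comparisons are against the
package's own exact solvers (truncated CME) or its Gillespie sampler;
passing them shows the approximation's internal accuracy on these model
classes, not anything about fits to experimental single-cell data.

## Known limitations

* Closed-form distributions exist only where the mapped network is the
  (non-bursty) telegraph model; bursty and oscillatory finite-time
  distributions are delivered by the exact linear-CME solve at the
  effective rates, which realizes the same approximation semi-analytically.
* The protein marginal of the mRNA–protein loop is available at moment
  level only.
* Accuracy degrades near a driving frequency resonant with the loop's
  intrinsic time scale, and grows worse with σ_b and with |ρ_u − ρ_b|;
  errors peak at intermediate times (both closure and averaging active).
* Networks with bimolecular reactions not of protein–promoter type are out
  of scope.
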