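# Methods

## The sampler

`tsmc` implements a sequential Monte Carlo sampler over a sequence of
posterior distributions π₁, π₂, …, π_T that live on spaces of different
(typically growing) dimension.  A population of P weighted particles is
carried from each posterior to the next in three stages:

1. **Transform.**  A deterministic map G carries each particle's state into
   the new space, after drawing fresh auxiliary variables u ~ ψ (the new
   coordinates) and, where several transformations are available, a route
   index l ~ ρ.  The pushed-forward density of the transformed particle —
   the importance proposal — is evaluated through the inverse image of the
   map(s), with the absolute Jacobian determinant of each route.
2. **Anneal.**  The gap between the pushed-forward proposal φ̃ and the new
   extended target is bridged geometrically, with intermediate densities
   φ̃^(1−γ) · π̃^γ for an increasing schedule of γ values.  The schedule is
   chosen adaptively: before each reweight the next γ is placed, by
   bisection, where the conditional effective sample size
   CESS = P (Σ w ω)² / Σ w ω² of the incremental weights ω would equal βP.
   After each reweight the ESS = 1/Σ w² is checked and the population is
   resampled by stratified resampling when it falls below αP; then each
   particle is moved by a few MCMC sweeps invariant for the current bridged
   density.
3. **Accumulate evidence.**  Each reweight appends the log of the
   weighted mean incremental weight; the running sum (plus the known log Z
   of the initial distribution) is an estimate of the log normalising
   constant of the current target, so the sampler yields the marginal
   likelihood of every model it visits and hence all Bayes factors.

Weight arithmetic is done entirely in the log domain.  The formal "fill in"
variables that pad every space to a common maximal dimension cancel
analytically in all weight updates and are never instantiated.

### Route handling: conditional vs marginal

When M routes are available the sampler either retains the sampled route
with the particle (conditional weight update) or sums the proposal density
over every route whose inverse image contains the state (marginalised,
Rao-Blackwellised update).  Within any transformed state the conditional
weights average exactly to the marginal weight under the route posterior, so
by the law of total variance the marginal update never has larger weight
variance; the test suite verifies the identity by enumeration.  With one
route the two coincide.

For the generic bijective-route bridge the retained route's prior mass
appears identically in the extended target and the proposal, so it is
omitted from both.  For the mixture split the tag retained in conditional
mode is the *pair of child components* (the split rank alone no longer
identifies the inverse image once MCMC has moved the state); the retained
pair carries uniform mass 1/C(t+1, 2) in the extended target and the route
prior 1/t stays in the proposal — both constants are kept explicit because
the tag space is finer than the route space.  The moment-matching merge
inverse exists for *every* component pair (the merged variance is the
within-plus-between decomposition, so the recovered auxiliary coordinates
always land in (0,1)), which keeps the conditional update unbiased.

A birth has no free route choice: the insertion rank of the new component is
determined by the ordering sort.  The exact density of the transformed state
is therefore the sum over all t+1 candidate ranks of Jacobian-corrected
inverse-image terms, and "conditional" and "marginal" birth coincide.

### Numerical choices

- γ-bisection: interval tolerance 1e-8, at most 60 iterations, minimum step
  1e-6, capped at γ = 1 (reached directly when CESS(1) ≥ βP).  The realised
  CESS at accepted intermediate γ values then matches βP to ~1e-3 P.
- Particles whose transformed value leaves the support of the new target
  get weight exactly zero (no exception), as do particles with NaN
  densities; a bridge aborts only when *every* particle dies.
- Stratified resampling draws one uniform per stratum ((i−1)/P, i/P]; with
  uniform weights it reduces to the identity.
- One numpy `Generator` drives a run, consumed in fixed particle order, so
  a seed reproduces a run bit-for-bit.
- MCMC proposal scales are refreshed from the weighted particle population
  before each move step (2.38 × weighted standard deviation per coordinate,
  floored away from zero).

### Bias of the adaptive schedule

With a *fixed* annealing schedule the linear-domain evidence estimator is
exactly unbiased, and the test suite confirms this on a tractable Gaussian
bridge.  Choosing the schedule adaptively from the same weights that enter
the increments introduces a small finite-P bias (measured ≈ −1% at P = 200,
β = 0.99 on a bridge between unit Gaussians three standard deviations
apart; larger for coarser β).  This is a known property of adaptive SMC,
vanishing as P grows, and is documented rather than corrected.

## Gaussian mixtures

The t-component model has ordered means μ₁ < … < μ_t, precisions τ, and
weights ν on the simplex; the likelihood is the plain mixture density
(no latent allocations).  Priors are calibrated from the data (mean m,
range S): μ ~ N(m, S²), τ ~ Gamma(2, 2S²/100) (shape/rate),
ν ~ Dirichlet(1, …, 1).  The ordering constraint removes label switching;
it is enforced by an indicator in the posterior, by re-sorting components
after every transformation (a measure-preserving permutation), and by
rejection inside the MCMC kernel.

Transformations between models:

- **Birth**: a new component drawn from its prior with a stick-breaking
  Beta(1, t) weight; existing weights scale by (1 − ν_new), giving
  log |J| = (t−1) log(1 − ν_new).
- **Split**: the classical moment-matching construction — child weights
  ν u₁ / ν(1−u₁), means μ ∓ u₂ σ √(ν₂/ν₁) (and its mirror), variances
  u₃(1−u₂²)σ²ν/ν₁ and (1−u₃)(1−u₂²)σ²ν/ν₂ with u₁, u₂ ~ Beta(2,2),
  u₃ ~ Uniform.  The parent's weight and first two moments are preserved.
  The analytic Jacobian, expressed in the precision parameterisation, is
  verified against finite differences in the tests.

Per-model evidence can also be computed by annealing each model from its
ordered prior to its posterior with the same adaptive machinery ("SMC2"),
which doubles as the way model 1 is initialised for the trans-dimensional
runs.  On well-separated data the prior-birth proposal barely overlaps the
posterior, so the birth bridge needs a much finer schedule (β ≈ 0.99) than
the split bridge to tame its weight tails — the number of intermediate
distributions the adaptation spends is itself the diagnostic.

The MCMC kernel is one Metropolis-within-Gibbs sweep: a Gaussian random walk
per mean (ordering violations rejected outright), a log-scale walk per
precision, and a joint random walk on the additive log-ratio transform of
the weights (Jacobian Πν).

## Coalescent genealogies

The genealogy of t sequences is an ultrametric binary tree: while a
lineages remain they coalesce at rate C(a,2) (time in coalescent units), so
the joint density of topology and heights under the uniform-pair-merge
convention is exp(−Σ_a C(a,2) l^(a)).  Sequences evolve under Jukes-Cantor
with θ/2 expected substitutions per site per unit branch time and uniform
root frequencies; θ carries a Gamma(1, 5) prior.  The likelihood is computed
by Felsenstein pruning over unique site patterns (compression is
bit-identical and cached per leaf subset).

A new sequence is absorbed by attaching its leaf to a proposed lineage at a
proposed height:

- the lineage is drawn with probability ∝ [(Nθ/(t+Nθ))^{M_s}]^power, M_s
  the SNP distance to leaf s (power 0 = uniform, larger powers more
  concentrated);
- the height comes from a log-normal Laplace approximation of the pairwise
  JC likelihood of the new sequence and the chosen leaf as a function of
  log-height.  The pairwise likelihood depends on θh only, so the fit is
  done once per candidate leaf at unit θ (analytic mode d̂/θ with
  d̂ = −(3/4)log(1 − 4p̂/3); curvature by central differences) and shifted
  by −log θ per particle.  Saturated or zero-mismatch pairs fall back to
  Exp(1), which is also available as a deliberately flat alternative.

The proposal density in the weight update marginalises the lineage over the
inverse image Λ of the attachment — exactly the leaves of the new leaf's
sibling subtree (all previous leaves when the attachment is above the old
root).  No Jacobian arises: the attachment is measure-preserving on
existing coordinates.  Model 1 needs no annealing: the single-sequence
posterior is the θ prior times the constant (1/4)^N likelihood, so
Z₁ = (1/4)^N exactly.

The MCMC kernel sweeps: truncated Gaussian walks on non-root coalescence
heights, a log-scale walk on the TMRCA, a nearest-neighbour interchange
(chosen over height-restricted subtree-prune-regraft: it is the
regraft-to-adjacent-edge special case, symmetric, and adequate at these
tree sizes), a log-scale walk on θ, and a joint "ridge" move that scales
all heights by c while dividing θ by c — the likelihood depends on θ ×
duration products, so this move traverses the height-θ ridge that
otherwise throttles θ mixing.  After the last bridge a few extra
rejuvenation sweeps at the full posterior (default 5) sharpen quantile and
consensus estimates; they do not touch the evidence.

Sequence orderings ("nearest"/"furthest" greedy SNP-distance orderings, or
as given) and weighted majority-rule consensus trees (strict-majority
clades, which are always mutually compatible) complete the online-inference
workflow.

## Synthetic data

The generators draw from exactly the models above: Kingman trees via
Exp(C(a,2)) waiting times and uniform pair merges; sequences by sampling
the JC transition matrix per branch (keep with probability e^{−4d/3}, else
redraw uniformly — identical in distribution to event-based simulation);
mixture data by component draws.  They emulate the study conditions used
throughout the tests (e.g. 20 points from a ±2 two-component mixture; n = 8
leaves, N = 500 sites, θ = 0.05).  What they deliberately do not emulate:
recombination, rate heterogeneity, indels, non-constant population size,
model misspecification of any kind.  Passing tests therefore demonstrate
correctness of the samplers under the assumed models, not robustness of the
models themselves on real data.

## Problem sizes used in the checks

The statistical test suite and the acceptance script run at desk scale,
chosen once: evidence unbiasedness with P = 200 over 100 runs; mixture
Bayes factors on N = 20 points with P = 96 over 50 seeds against a
conjugate-quadrature / 4×10⁵-draw importance-sampling oracle; 3-sequence
evidence with P = 100 over 25 seeds against a 48³-node quadrature; θ
coverage and topology recovery with P = 128/96 over 20 seeds each.  The
library defaults mirror the larger settings of the original experiments
(P = 500, β = 0.99 for mixtures; P = 250, β = 0.95 for the coalescent).

## Known limitations

- Adaptive-schedule evidence estimates carry the small finite-P bias noted
  above.
- The conditional split update is exact but noisier than the marginal one;
  on well-separated data the birth bridge without a fine schedule produces
  heavy-tailed weights whose linear-domain mean converges very slowly — use
  the split move or a large β for evidence work.
- The NNI move explores topology space more slowly than full
  subtree-prune-regraft would on large trees.
- Only Jukes-Cantor substitution, constant population size, and strictly
  binary ultrametric genealogies are supported; decreasing-dimension moves
  (sequence removal) are not implemented.
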